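"""High-level orchestration: simulate -> classify -> preprocess ->
discover -> score -> group.

Each step is a thin, testable function over the module APIs; the CLI
and the analysis scripts call these rather than re-wiring the modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import preprocess as pp
from .annotation import SpotClass, classify_spots_frame
from .discovery import DiscoveryParams, Signature, discover_signatures
from .groups import (
    assign_pseudobulk_groups,
    composition_by_score_class,
    metabolite_group_summary,
)
from .io import CountMatrix
from .ssgsea import score_signature

logger = logging.getLogger(__name__)


def classify_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Add a ``spot_class`` column from the annotation-fraction columns."""
    out = spots.copy()
    out["spot_class"] = [c.value for c in classify_spots_frame(spots)]
    n_excl = int((out["spot_class"] == SpotClass.EXCLUDED.value).sum())
    logger.info("classified %d spots (%d excluded)", len(out), n_excl)
    return out


@dataclass
class PreprocessedCohort:
    """Matrices and metadata after spot classification and QC."""

    counts: CountMatrix           # filtered raw counts
    spots: pd.DataFrame           # filtered metadata with spot_class
    normalized: object            # per-cell normalized counts (sparse)
    log_matrix: object            # log10(c * 1e4 + 1) (sparse)
    qc: pp.QCReport


def preprocess_cohort(
    counts: CountMatrix,
    spots: pd.DataFrame,
    drop_excluded: bool = True,
    **qc_kwargs,
) -> PreprocessedCohort:
    """Drop excluded spots, apply spot QC and the gene filter, normalize.

    Both QC masks are computed once on the post-classification matrix
    and applied together.
    """
    spots = spots.loc[counts.barcodes]
    if drop_excluded:
        keep = (spots["spot_class"] != SpotClass.EXCLUDED.value).to_numpy()
        logger.info("dropping %d excluded spots", int((~keep).sum()))
        counts = counts.subset(spot_mask=keep)
        spots = spots.loc[keep]

    qc = pp.run_qc(counts.matrix, spots["cell_count"].to_numpy(), **qc_kwargs)
    logger.info(
        "QC: %d/%d spots kept, %d/%d genes kept",
        qc.n_spots_kept, len(spots), qc.n_genes_kept, counts.shape[0],
    )
    counts = counts.subset(gene_mask=qc.gene_keep, spot_mask=qc.spot_keep)
    spots = spots.loc[qc.spot_keep]
    normalized, log_matrix = pp.normalize_and_log(
        counts.matrix, spots["cell_count"].to_numpy()
    )
    return PreprocessedCohort(counts, spots, normalized, log_matrix, qc)


def discover(
    cohort: PreprocessedCohort,
    panel=None,
    params: Optional[DiscoveryParams] = None,
):
    """Run signature discovery on a preprocessed cohort."""
    return discover_signatures(
        cohort.counts.matrix,
        cohort.normalized,
        cohort.log_matrix,
        cohort.counts.gene_names,
        cohort.spots["spot_class"].to_numpy(),
        cohort.spots["status"].to_numpy(),
        cohort.spots["sample_id"].to_numpy(),
        cohort.spots["patient_id"].to_numpy(),
        panel=panel,
        params=params,
    )


def score(
    cohort: PreprocessedCohort,
    signatures: Dict[str, Signature],
    mode: str = "st",
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    weight_exponent: float = 0.0,
    center: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Score each signature over all spots with permutation significance."""
    out = {}
    for name, sig in signatures.items():
        out[name] = score_signature(
            cohort.counts.matrix,
            sig,
            cohort.counts.gene_names,
            cohort.counts.barcodes,
            mode=mode,
            n_permutations=n_permutations,
            weight_exponent=weight_exponent,
            center=center,
            seed=seed,
        )
    return out


@dataclass
class GroupResults:
    pseudobulk: pd.Series
    composition: Dict[str, pd.DataFrame] = field(default_factory=dict)
    metabolite_summary: Dict[str, pd.DataFrame] = field(default_factory=dict)


def group(
    cohort: PreprocessedCohort,
    scores: Dict[str, pd.DataFrame],
    metabolites: Optional[pd.DataFrame] = None,
) -> GroupResults:
    """Pseudo-bulk grouping plus per-signature composition/metabolite tables."""
    spots = cohort.spots.rename(columns={})
    pseudo = assign_pseudobulk_groups(
        spots[["status", "sample_type", "spot_class"]]
    )
    res = GroupResults(pseudobulk=pseudo)
    for name, score_frame in scores.items():
        aligned = score_frame.reindex(spots.index)
        res.composition[name] = composition_by_score_class(
            aligned["significance_class"].to_numpy(),
            spots["spot_class"].to_numpy(),
        )
        if metabolites is not None:
            res.metabolite_summary[name] = metabolite_group_summary(
                metabolites.reindex(spots.index),
                aligned["significance_class"],
                mode="spatial",
            )
    return res
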