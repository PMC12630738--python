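"""Pseudo-bulk grouping, score-class composition, and metabolite summaries.

Spots are aggregated into ten pseudo-bulk groups from three levels:
patient status (A = aggressive, I = non-aggressive), sample class
(C = cancer or normal-adjacent, N = normal) and spot class (c = cancer
[all ISUP grades merged], g = non-cancerous gland, s = stroma).  Normal
samples carry no cancer spots, so the code set is
{CAc, CAg, CAs, CIc, CIg, CIs, NAg, NAs, NIg, NIs}.  Lymphocyte-
enriched stroma, perineural invasion, lymphocyte and excluded spots do
not enter any group.

The module also summarizes per-spot metabolite intensities by score
group (median, quartiles, n) and computes Spearman correlation tables
between covariates (e.g. deconvolved cell-type fractions) and
signature scores.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation import SpotClass, ISUP_CLASSES
from .ssgsea import HIGH, LOW, NOT_SIGNIFICANT

logger = logging.getLogger(__name__)

PSEUDOBULK_CODES = (
    "CAc", "CAg", "CAs", "CIc", "CIg", "CIs", "NAg", "NAs", "NIg", "NIs",
)

CANCER_SAMPLE_TYPES = ("cancer", "normal_adjacent")
NORMAL_SAMPLE_TYPE = "normal"

AGGRESSIVE = "aggressive"
NON_AGGRESSIVE = "non_aggressive"


class GroupError(ValueError):
    """Raised on invalid grouping input."""


def assign_pseudobulk_group(
    status: str,
    sample_type: str,
    spot_class: str,
    include_uncertain_grades: bool = False,
) -> Optional[str]:
    """Map one spot to its pseudo-bulk code, or ``None`` if excluded.

    Cancer and normal-adjacent samples merge into the 'C' sample class;
    all certain ISUP grades merge into the 'c' spot class.  Spots with
    uncertain grading (ISUPX/ISUPY) are excluded by default
    (``include_uncertain_grades=True`` folds them into 'c').  A cancer
    spot inside a normal sample has no defined code and is excluded
    with a warning.
    """
    if status == AGGRESSIVE:
        level2 = "A"
    elif status == NON_AGGRESSIVE:
        level2 = "I"
    else:
        raise GroupError(f"unknown patient status {status!r}")
    if sample_type in CANCER_SAMPLE_TYPES:
        level1 = "C"
    elif sample_type == NORMAL_SAMPLE_TYPE:
        level1 = "N"
    else:
        raise GroupError(f"unknown sample type {sample_type!r}")

    cls = SpotClass(spot_class)
    cancer_classes = set(ISUP_CLASSES)
    if include_uncertain_grades:
        cancer_classes |= {SpotClass.ISUPX, SpotClass.ISUPY}
    if cls in cancer_classes:
        level3 = "c"
    elif cls is SpotClass.NCG:
        level3 = "g"
    elif cls is SpotClass.STROMA:
        level3 = "s"
    else:
        return None

    if level1 == "N" and level3 == "c":
        logger.warning(
            "cancer spot in a normal sample has no pseudo-bulk code; excluded"
        )
        return None
    return level1 + level2 + level3


def assign_pseudobulk_groups(spots: pd.DataFrame, **kwargs) -> pd.Series:
    """Vector version over a spots table with status/sample_type/spot_class."""
    return pd.Series(
        [
            assign_pseudobulk_group(
                r.status, r.sample_type, r.spot_class, **kwargs
            )
            for r in spots.itertuples(index=False)
        ],
        index=spots.index,
        name="pseudobulk_group",
    )


#: Histology categories used when reporting score-class composition.
#: "High grade" cancer follows the ISUP >= 3 convention and includes
#: perineural invasion.
DEFAULT_COMPOSITION_CATEGORIES = {
    SpotClass.STROMA.value: "stroma",
    SpotClass.LYMPH_ENRICHED_STROMA.value: "stroma",
    SpotClass.NCG.value: "NCG",
    SpotClass.ISUP1.value: "cancer_low_grade",
    SpotClass.ISUP2.value: "cancer_low_grade",
    SpotClass.ISUP3.value: "cancer_high_grade",
    SpotClass.ISUP4.value: "cancer_high_grade",
    SpotClass.ISUP5.value: "cancer_high_grade",
    SpotClass.PNI.value: "cancer_high_grade",
    SpotClass.ISUPX.value: "cancer_high_grade",
    SpotClass.ISUPY.value: "cancer_low_grade",
    SpotClass.LYMPHOCYTES.value: "lymphocytes",
}


def composition_by_score_class(
    significance_classes: Sequence[str],
    spot_classes: Sequence[str],
    categories: Optional[dict] = None,
) -> pd.DataFrame:
    """Percentage histology breakdown per significance class.

    Returns a frame with one row per observed significance class and
    one column per reporting category; each row sums to 100.  Empty
    significance classes are simply absent.
    """
    sig = np.asarray(significance_classes)
    cls = np.asarray(spot_classes)
    if sig.size != cls.size:
        raise GroupError("label vectors differ in length")
    cats = categories or DEFAULT_COMPOSITION_CATEGORIES
    mapped = pd.Series(cls).map(cats)
    frame = pd.DataFrame({"sig": sig, "cat": mapped}).dropna()
    counts = frame.groupby(["sig", "cat"], observed=True).size().unstack(
        fill_value=0
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def metabolite_group_summary(
    metabolites: pd.DataFrame,
    group_labels: pd.Series,
    mode: str = "spatial",
) -> pd.DataFrame:
    """Median, quartiles and n per metabolite per group.

    ``mode='bulk'`` first min-max scales each metabolite's raw
    integrals to [0, 1] across units; ``mode='spatial'`` consumes the
    relative intensities as provided.  Units without a group label are
    dropped with a warning.
    """
    if mode not in ("spatial", "bulk"):
        raise GroupError(f"unknown mode {mode!r}")
    groups = group_labels.reindex(metabolites.index)
    missing = groups.isna()
    if missing.any():
        logger.warning("%d units without a group label dropped",
                       int(missing.sum()))
    vals = metabolites.loc[~missing].copy()
    groups = groups[~missing]

    if mode == "bulk":
        for col in vals.columns:
            x = vals[col].to_numpy(dtype=float)
            lo, hi = np.nanmin(x), np.nanmax(x)
            vals[col] = 0.0 if hi == lo else (x - lo) / (hi - lo)

    rows = []
    for met in vals.columns:
        for grp, sub in vals.groupby(groups, observed=True)[met]:
            q1, med, q3 = np.nanpercentile(sub.to_numpy(dtype=float),
                                           [25, 50, 75])
            rows.append((met, grp, med, q1, q3, int(sub.notna().sum())))
    return pd.DataFrame(
        rows, columns=["metabolite", "group", "median", "q1", "q3", "n"]
    )


def spearman_correlations(
    covariates: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation of every covariate with every score.

    Ties are mid-ranked; a constant column has no defined rank
    correlation and is reported as NaN.  Requires at least 3 paired
    observations.
    """
    if len(covariates) != len(scores):
        raise GroupError("covariates and scores differ in length")
    if len(covariates) < 3:
        raise GroupError("need at least 3 paired observations")
    out = pd.DataFrame(index=covariates.columns, columns=scores.columns,
                       dtype=float)
    for cov in covariates.columns:
        x = covariates[cov].to_numpy(dtype=float)
        for sc in scores.columns:
            y = scores[sc].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                out.loc[cov, sc] = np.nan
            else:
                out.loc[cov, sc] = spearmanr(x, y).statistic
    return out
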