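"""Two-track gene selection and sparsity-aware ranking of discriminative genes.

Candidate genes are collected per histopathology class along two
variability tracks (highest relative standard deviation; highest
bin-normalized dispersion z-score) and one deregulation track (mean
log-expression difference between aggressive and non-aggressive
patients larger than ``delta`` with a bounded RSD in the non-aggressive
group).  Candidates surviving a provenance filter are ranked by the
average of two min-max normalized statistics designed for ~90% sparse
spot counts:

* ZFCMD — zero-count-free median difference: the absolute difference
  of the group medians of strictly positive normalized counts, which
  captures intensity differences without being flattened by zeros;
* NZCSCD — non-zero-count spot count difference: the absolute
  difference in the number of expressing spots between groups, scaled
  by their sum, a frequency-of-detection measure in [0, 1].

Genes below the median rank-score are pruned; an optional user panel
(e.g. all detected chemokines) is appended before the final filter and
ranking.  The surviving genes are assembled into two signatures: genes
deregulated in the same direction in every spot class ("aggressive
cancer"-like, APC) and genes deregulated exclusively in non-cancerous
gland spots ("chemokine-enriched gland"-like, CEG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import SpotClass

logger = logging.getLogger(__name__)

AGGRESSIVE = "aggressive"
NON_AGGRESSIVE = "non_aggressive"


class DiscoveryError(ValueError):
    """Raised on invalid input to signature discovery."""


@dataclass
class Signature:
    """A named gene set split into up- and down-regulated members."""

    name: str
    up_genes: Set[str] = field(default_factory=set)
    down_genes: Set[str] = field(default_factory=set)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise DiscoveryError(
                f"signature {self.name}: genes in both up and down: {overlap}"
            )

    @property
    def genes(self) -> Set[str]:
        return self.up_genes | self.down_genes

    @property
    def n_genes(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def _as_dense(mat) -> np.ndarray:
    if sp.issparse(mat):
        return np.asarray(mat.todense())
    return np.asarray(mat, dtype=float)


def rsd(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Relative standard deviation (sample sd / sample mean).

    A zero mean means the gene is constant zero in this class and
    carries no signal; its RSD is defined as 0.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=axis)
    n = values.shape[axis]
    sd = values.std(axis=axis, ddof=1) if n > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), 0.0)
    return out


def _top_k_with_ties(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest finite values, keeping ties at the cut."""
    finite = np.isfinite(values)
    if finite.sum() == 0 or k <= 0:
        return np.empty(0, dtype=int)
    vals = np.where(finite, values, -np.inf)
    order = np.argsort(vals, kind="stable")[::-1]
    if finite.sum() <= k:
        return order[: finite.sum()]
    cut = vals[order[k - 1]]
    return np.flatnonzero(vals >= cut)


def binned_dispersion_z(
    log_matrix: np.ndarray, n_bins: int = 20, dispersion: str = "mean_var"
) -> np.ndarray:
    """Bin-standardized dispersion z-scores for each gene.

    ``dispersion='mean_var'`` uses mean/variance; ``'var_mean'`` uses
    variance/mean.  Genes are binned by mean expression into ``n_bins``
    equal-width bins; bins holding fewer than two genes are merged into
    the nearest lower populated bin so every z-score is defined.
    Genes with zero variance get a NaN dispersion and are never selected.
    """
    m = _as_dense(log_matrix)
    mean = m.mean(axis=1)
    var = m.var(axis=1, ddof=1) if m.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        if dispersion == "mean_var":
            disp = np.where(var > 0, mean / np.where(var > 0, var, 1.0), np.nan)
        elif dispersion == "var_mean":
            disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
        else:
            raise DiscoveryError(f"unknown dispersion mode {dispersion!r}")

    lo, hi = mean.min(), mean.max()
    if hi <= lo:
        bins = np.zeros(mean.size, dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(mean, edges[1:-1]), 0, n_bins - 1)

    # merge sparse bins downward so each used bin has >= 2 members
    valid = np.isfinite(disp)
    for b in range(n_bins):
        members = np.flatnonzero((bins == b) & valid)
        if 0 < members.size < 2:
            target = b - 1
            while target >= 0 and not ((bins == target) & valid).any():
                target -= 1
            if target < 0:
                target = b + 1
                while target < n_bins and not ((bins == target) & valid).any():
                    target += 1
            if 0 <= target < n_bins and target != b:
                bins[members] = target

    z = np.full(mean.size, np.nan)
    for b in np.unique(bins[valid]):
        members = np.flatnonzero((bins == b) & valid)
        if members.size < 2:
            continue
        d = disp[members]
        sd = d.std(ddof=1)
        z[members] = 0.0 if sd == 0 else (d - d.mean()) / sd
    return z


def select_variable_genes(
    log_matrix,
    class_labels: Sequence[str],
    genes: Sequence[str],
    k: int = 5,
    n_bins: int = 20,
    dispersion: str = "mean_var",
) -> Dict[str, Set[str]]:
    """Per-class top-k genes by RSD and by binned dispersion z-score.

    Returns a mapping gene -> set of origin tags like ``"rsd:STROMA"``.
    Classes with fewer than two spots are skipped with a warning.
    """
    m = _as_dense(log_matrix)
    labels = np.asarray(class_labels)
    genes = np.asarray(genes)
    out: Dict[str, Set[str]] = {}
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            logger.warning("class %s has < 2 spots; skipped", cls)
            continue
        sub = m[:, idx]
        for gi in _top_k_with_ties(rsd(sub, axis=1), k):
            out.setdefault(genes[gi], set()).add(f"rsd:{cls}")
        z = binned_dispersion_z(sub, n_bins=n_bins, dispersion=dispersion)
        for gi in _top_k_with_ties(z, k):
            out.setdefault(genes[gi], set()).add(f"dispersion:{cls}")
    return out


def select_deregulated_genes(
    log_matrix,
    status: Sequence[str],
    class_labels: Sequence[str],
    genes: Sequence[str],
    delta: float = 1.0,
    rsd_max: float = 0.20,
) -> Dict[str, Set[str]]:
    """Per-class genes deregulated between patient groups.

    A gene is selected in a class when the absolute difference of mean
    log expression between aggressive and non-aggressive spots exceeds
    ``delta`` (1 on the log10 scale: a ten-fold change) and its RSD in
    the non-aggressive group of that class is at most ``rsd_max``.
    """
    m = _as_dense(log_matrix)
    status = np.asarray(status)
    labels = np.asarray(class_labels)
    genes = np.asarray(genes)
    out: Dict[str, Set[str]] = {}
    for cls in pd.unique(labels):
        in_cls = labels == cls
        agg = np.flatnonzero(in_cls & (status == AGGRESSIVE))
        non = np.flatnonzero(in_cls & (status == NON_AGGRESSIVE))
        if agg.size < 2 or non.size < 2:
            logger.warning(
                "class %s lacks spots from one patient group; skipped", cls
            )
            continue
        dmean = m[:, agg].mean(axis=1) - m[:, non].mean(axis=1)
        rsd_non = rsd(m[:, non], axis=1)
        hits = np.flatnonzero((np.abs(dmean) > delta) & (rsd_non <= rsd_max))
        for gi in hits:
            out.setdefault(genes[gi], set()).add(f"deregulated:{cls}")
    return out


def provenance_filter(
    candidate_genes: Iterable[str],
    raw,
    genes: Sequence[str],
    sample_ids: Sequence[str],
    patient_ids: Sequence[str],
    max_share: float = 0.75,
    min_spot_fraction: float = 0.025,
) -> pd.DataFrame:
    """Drop genes whose observations are concentrated or too rare.

    An "observation" is a spot with a nonzero raw count for the gene.
    A gene is removed when >= ``max_share`` of its observations come
    from one sample or one patient, or when it is observed in
    <= ``min_spot_fraction`` of all spots.

    Returns a frame indexed by gene with columns ``max_sample_share``,
    ``max_patient_share``, ``spot_fraction`` and boolean ``keep``.
    """
    genes = list(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_ids = np.asarray(sample_ids)
    patient_ids = np.asarray(patient_ids)
    n_spots = sample_ids.size
    mat = raw.tocsr() if sp.issparse(raw) else np.asarray(raw)

    rows = []
    for g in candidate_genes:
        gi = gene_index.get(g)
        if gi is None:
            continue
        row = mat[gi].toarray().ravel() if sp.issparse(mat) else mat[gi]
        nz = np.flatnonzero(row)
        if nz.size == 0:
            rows.append((g, 1.0, 1.0, 0.0, False))
            continue
        s_share = pd.Series(sample_ids[nz]).value_counts().iloc[0] / nz.size
        p_share = pd.Series(patient_ids[nz]).value_counts().iloc[0] / nz.size
        frac = nz.size / n_spots
        keep = (
            s_share < max_share
            and p_share < max_share
            and frac > min_spot_fraction
        )
        rows.append((g, s_share, p_share, frac, keep))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "max_sample_share",
            "max_patient_share",
            "spot_fraction",
            "keep",
        ],
    ).set_index("gene")


def zfcmd(c: np.ndarray, is_aggressive: np.ndarray) -> float:
    """Zero-count-free median difference for one gene.

    Absolute difference of the medians of strictly positive normalized
    counts per patient group.  A group with no positive spot contributes
    a median of 0, preserving signal for group-exclusive genes.
    """
    c = np.asarray(c, dtype=float)
    is_aggressive = np.asarray(is_aggressive, dtype=bool)
    pos_a = c[is_aggressive & (c > 0)]
    pos_n = c[~is_aggressive & (c > 0)]
    med_a = float(np.median(pos_a)) if pos_a.size else 0.0
    med_n = float(np.median(pos_n)) if pos_n.size else 0.0
    return abs(med_a - med_n)


def nzcscd(c: np.ndarray, is_aggressive: np.ndarray) -> float:
    """Non-zero-count spot count difference for one gene, in [0, 1]."""
    c = np.asarray(c, dtype=float)
    is_aggressive = np.asarray(is_aggressive, dtype=bool)
    n_a = int(np.count_nonzero(c[is_aggressive]))
    n_n = int(np.count_nonzero(c[~is_aggressive]))
    if n_a + n_n == 0:
        raise DiscoveryError("gene has no nonzero spot in either group")
    return abs(n_a - n_n) / (n_a + n_n)


def min_max(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant vector maps to 0.5.

    Mapping a degenerate metric to the neutral midpoint leaves the mean
    rank-score unaffected by that metric.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def class_delta_means(
    log_matrix,
    status: Sequence[str],
    class_labels: Sequence[str],
    genes: Sequence[str],
    min_spots_per_group: int = 10,
) -> pd.DataFrame:
    """Per-class mean log-expression difference (aggressive - non-aggressive).

    Classes with fewer than ``min_spots_per_group`` spots in either
    patient group are omitted (with a warning): their means are too
    unstable to vote on signature membership.
    """
    m = _as_dense(log_matrix)
    status = np.asarray(status)
    labels = np.asarray(class_labels)
    cols = {}
    for cls in pd.unique(labels):
        in_cls = labels == cls
        agg = in_cls & (status == AGGRESSIVE)
        non = in_cls & (status == NON_AGGRESSIVE)
        if agg.sum() < min_spots_per_group or non.sum() < min_spots_per_group:
            logger.warning(
                "class %s underpowered (%d agg / %d non-agg spots); "
                "omitted from signature assembly",
                cls, int(agg.sum()), int(non.sum()),
            )
            continue
        cols[str(cls)] = m[:, agg].mean(axis=1) - m[:, non].mean(axis=1)
    if not cols:
        raise DiscoveryError("no class has both patient groups represented")
    return pd.DataFrame(cols, index=list(genes))


def rank_prune_assemble(
    records: pd.DataFrame,
    delta_by_class: pd.DataFrame,
    delta_class: float = 0.1,
    apc_mode: str = "threshold",
    ncg_class: str = SpotClass.NCG.value,
) -> tuple:
    """Rank candidates, prune below-median genes, assemble signatures.

    ``records`` must carry columns ``zfcmd`` and ``nzcscd`` indexed by
    gene.  Each metric is min-max normalized over the candidate list
    and the rank-score is their mean; genes below the median rank-score
    are removed (ties at the median kept).

    APC-like membership (``apc_mode='threshold'``): the per-class mean
    difference has the same sign in every class and magnitude
    >= ``delta_class`` everywhere.  ``apc_mode='sign'`` requires sign
    consistency only (with a nonzero difference in every class).
    CEG-like membership: magnitude >= ``delta_class`` in non-cancerous
    gland spots and < ``delta_class`` in every other class.

    Returns ``(apc_signature, ceg_signature, ranked_records)``.
    """
    if records.empty:
        raise DiscoveryError("empty candidate list")
    if apc_mode not in ("threshold", "sign"):
        raise DiscoveryError(f"unknown apc_mode {apc_mode!r}")

    rec = records.copy()
    rec["minmax_zfcmd"] = min_max(rec["zfcmd"].to_numpy())
    rec["minmax_nzcscd"] = min_max(rec["nzcscd"].to_numpy())
    rec["rank_score"] = (rec["minmax_zfcmd"] + rec["minmax_nzcscd"]) / 2.0
    median_score = rec["rank_score"].median()
    rec["kept"] = rec["rank_score"] >= median_score

    apc = Signature("APC_like")
    ceg = Signature("CEG_like")
    if ncg_class not in delta_by_class.columns:
        logger.warning(
            "class %s absent from delta table; CEG-like assembly skipped",
            ncg_class,
        )
    other_cols = [c for c in delta_by_class.columns if c != ncg_class]

    for gene in rec.index[rec["kept"]]:
        if gene not in delta_by_class.index:
            continue
        d = delta_by_class.loc[gene]
        signs = np.sign(d.to_numpy())
        unanimous = np.all(signs == signs[0]) and signs[0] != 0
        if apc_mode == "threshold":
            unanimous = unanimous and bool((d.abs() >= delta_class).all())
        if unanimous:
            target = apc.up_genes if signs[0] > 0 else apc.down_genes
            target.add(gene)
            apc.provenance[gene] = str(rec.loc[gene].get("origin", ""))
            continue
        if ncg_class in d.index:
            in_ncg = abs(d[ncg_class]) >= delta_class
            quiet_elsewhere = bool(
                (d[other_cols].abs() < delta_class).all()
            ) if other_cols else True
            if in_ncg and quiet_elsewhere:
                target = ceg.up_genes if d[ncg_class] > 0 else ceg.down_genes
                target.add(gene)
                ceg.provenance[gene] = str(rec.loc[gene].get("origin", ""))
    return apc, ceg, rec


@dataclass
class DiscoveryParams:
    """Tunable thresholds of the discovery pipeline with field defaults."""

    top_k: int = 5
    n_bins: int = 20
    dispersion: str = "mean_var"
    dereg_delta: float = 1.0
    rsd_max: float = 0.20
    max_share: float = 0.75
    min_spot_fraction: float = 0.025
    delta_class: float = 0.1
    apc_mode: str = "threshold"
    min_spots_per_group: int = 10


def discover_signatures(
    raw,
    normalized,
    log_matrix,
    genes: Sequence[str],
    class_labels: Sequence[str],
    status: Sequence[str],
    sample_ids: Sequence[str],
    patient_ids: Sequence[str],
    panel: Optional[Iterable[str]] = None,
    params: Optional[DiscoveryParams] = None,
) -> tuple:
    """Run the full discovery flow and return both signatures.

    Spots labeled EXCLUDED must be dropped by the caller.  ``panel`` is
    an optional gene list (e.g. all detected chemokines) appended to the
    preliminary candidates before the final provenance filter and
    ranking.  Returns ``(apc, ceg, records)`` where ``records`` is the
    full per-candidate statistics table.
    """
    p = params or DiscoveryParams()
    genes = list(genes)
    labels = np.asarray(class_labels)
    if (labels == SpotClass.EXCLUDED.value).any():
        raise DiscoveryError("drop EXCLUDED spots before discovery")

    variable = select_variable_genes(
        log_matrix, labels, genes, k=p.top_k, n_bins=p.n_bins,
        dispersion=p.dispersion,
    )
    dereg = select_deregulated_genes(
        log_matrix, status, labels, genes, delta=p.dereg_delta,
        rsd_max=p.rsd_max,
    )
    origins: Dict[str, Set[str]] = {}
    for src in (variable, dereg):
        for g, tags in src.items():
            origins.setdefault(g, set()).update(tags)
    logger.info(
        "preliminary list: %d variable + %d deregulated -> %d unique genes",
        len(variable), len(dereg), len(origins),
    )

    prov = provenance_filter(
        sorted(origins), raw, genes, sample_ids, patient_ids,
        max_share=p.max_share, min_spot_fraction=p.min_spot_fraction,
    )
    candidates = set(prov.index[prov["keep"]])

    if panel is not None:
        detected_panel = set(panel) & set(genes)
        for g in detected_panel:
            origins.setdefault(g, set()).add("panel")
        # re-run the filtering on the augmented list
        prov = provenance_filter(
            sorted(candidates | detected_panel), raw, genes, sample_ids,
            patient_ids, max_share=p.max_share,
            min_spot_fraction=p.min_spot_fraction,
        )
        candidates = set(prov.index[prov["keep"]])
    logger.info("%d candidates after provenance filter", len(candidates))
    if not candidates:
        raise DiscoveryError("no candidate genes survive the filters")

    gene_index = {g: i for i, g in enumerate(genes)}
    norm = normalized.tocsr() if sp.issparse(normalized) else np.asarray(normalized)
    is_agg = np.asarray(status) == AGGRESSIVE
    rows = []
    for g in sorted(candidates):
        gi = gene_index[g]
        c = norm[gi].toarray().ravel() if sp.issparse(norm) else norm[gi]
        rows.append((g, zfcmd(c, is_agg), nzcscd(c, is_agg),
                     ";".join(sorted(origins.get(g, set())))))
    records = pd.DataFrame(
        rows, columns=["gene", "zfcmd", "nzcscd", "origin"]
    ).set_index("gene")
    records = records.join(prov, how="left")

    deltas = class_delta_means(
        log_matrix, status, labels, genes,
        min_spots_per_group=p.min_spots_per_group,
    )
    apc, ceg, ranked = rank_prune_assemble(
        records, deltas, delta_class=p.delta_class, apc_mode=p.apc_mode,
    )
    logger.info(
        "signatures: APC-like %d up / %d down, CEG-like %d up / %d down",
        len(apc.up_genes), len(apc.down_genes),
        len(ceg.up_genes), len(ceg.down_genes),
    )
    return apc, ceg, ranked
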