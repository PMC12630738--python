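"""Sparsity-aware single-sample GSEA with a permutation null.

Scores are rank-based running-sum enrichment statistics computed per
unit (spot or bulk sample).  To cope with ~90% sparse spot data, the
expression matrix is first centered per gene, so that a gene with zero
counts in one spot but high expression elsewhere ranks low in that
spot, below genes that are near zero everywhere.

For a unit's expression vector the genes are sorted in decreasing
order and the score is the sum over ranks of the difference between
the weighted in-set empirical distribution function and the out-set
one.  With weight exponent ``w = 0`` (the default) the score depends
only on the ranks of the set members, so a single permutation null per
signature — built from ``n`` unique random gene rankings — serves
every unit, which is what makes 1000-permutation significance
affordable on tens of thousands of spots.

Up- and down-regulated signature parts are scored separately and
combined as ``(up - down) / 2``; combined scores are min-max scaled to
[-1000, 1000] across units.  One-sided empirical p-values (with an
add-one correction so Fisher's method never sees p = 0) for the up and
down parts are combined with Fisher's method; a unit is called HIGH or
LOW only when the combined p-value passes the mode-specific threshold
(0.05 / number of signature genes for spot data, 0.05 for bulk) and
the scaled score magnitude exceeds 200.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Set

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2

from .discovery import Signature

logger = logging.getLogger(__name__)

SCORE_BOUND = 1000.0
SCORE_CUTOFF = 200.0

HIGH = "HIGH"
LOW = "LOW"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


class ScoringError(ValueError):
    """Raised on invalid input to ssGSEA scoring."""


def center_matrix(matrix) -> np.ndarray:
    """Subtract the per-gene mean across units (rows = genes).

    Centering is refused for a single unit, where it would zero the
    matrix.  Idempotent up to floating point.
    """
    m = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix,
                   dtype=float)
    if m.ndim != 2:
        raise ScoringError("expected a genes x units matrix")
    if m.shape[1] < 2:
        raise ScoringError("centering needs at least 2 units")
    return m - m.mean(axis=1, keepdims=True)


def _rank_order(values: np.ndarray) -> np.ndarray:
    """Gene indices sorted by decreasing value; ties broken by index."""
    return np.argsort(-values, kind="stable")


def ssgsea_raw_score(
    values: np.ndarray, in_set: np.ndarray, weight_exponent: float = 0.0
) -> float:
    """Running-sum enrichment score of one gene set in one unit.

    ``values`` is the (centered) expression vector over the gene
    universe, ``in_set`` a boolean membership mask.  Sorting genes by
    decreasing value, the score accumulates at every rank the
    difference between the in-set ECDF (weighted by
    ``|value|^weight_exponent``, normalized within the set) and the
    uniform out-set ECDF; it is positive when set members concentrate
    at the top of the ranking.  With ``weight_exponent = 0`` the score
    is a pure rank statistic, invariant to monotone transforms.
    """
    values = np.asarray(values, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    G = values.size
    m = int(in_set.sum())
    if m == 0:
        raise ScoringError("empty gene set")
    if m == G:
        raise ScoringError("gene set equals the gene universe")
    order = _rank_order(values)
    # rank (1-based) of each gene in the sorted order
    ranks = np.empty(G, dtype=float)
    ranks[order] = np.arange(1, G + 1)
    tail = G - ranks + 1.0  # number of ranks at which the gene contributes

    if weight_exponent == 0.0:
        w = np.full(m, 1.0 / m)
    else:
        a = np.abs(values[in_set]) ** weight_exponent
        total = a.sum()
        w = np.full(m, 1.0 / m) if total == 0 else a / total
    score_in = float((w * tail[in_set]).sum())
    score_out = float(tail[~in_set].sum() / (G - m))
    return score_in - score_out


@dataclass
class PermutationNull:
    """Null score samples from unique random gene rankings.

    ``null_up`` and ``null_down`` hold, for each of ``n_permutations``
    distinct permutations of the gene universe, the enrichment scores
    of an up-sized and a down-sized set read off the permuted ranking
    (the two share permutations, mirroring the paired up/down scoring
    of a real unit).
    """

    universe_size: int
    up_size: int
    down_size: int
    n_permutations: int
    null_up: np.ndarray
    null_down: np.ndarray
    seed: Optional[int] = None

    @classmethod
    def build(
        cls,
        universe_size: int,
        up_size: int,
        down_size: int,
        n_permutations: int = 1000,
        rng: Optional[np.random.Generator] = None,
        seed: Optional[int] = None,
    ) -> "PermutationNull":
        """Sample ``n_permutations`` pairwise-distinct rankings.

        Uniqueness is enforced by rejection on permutation hashes.  The
        score of a set under a permuted ranking depends only on the
        ranks landing in the set, computed with the rank-only (w = 0)
        statistic.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        G = universe_size
        for size, label in ((up_size, "up"), (down_size, "down")):
            if size < 0 or size >= G:
                raise ScoringError(
                    f"{label} set size {size} invalid for universe {G}"
                )
        import math

        if G <= 20 and n_permutations > math.factorial(G):
            raise ScoringError(
                f"cannot draw {n_permutations} unique permutations of "
                f"{G} genes"
            )
        seen: Set[int] = set()
        ups = np.empty(n_permutations)
        downs = np.empty(n_permutations)
        i = 0
        attempts = 0
        while i < n_permutations:
            perm = rng.permutation(G)
            h = hash(perm.tobytes())
            attempts += 1
            if h in seen:
                continue
            seen.add(h)
            ups[i] = _score_from_ranks(perm[:up_size] + 1, G, up_size) \
                if up_size else np.nan
            # disjoint draw for the down part of the same permutation
            downs[i] = _score_from_ranks(
                perm[up_size:up_size + down_size] + 1, G, down_size
            ) if down_size else np.nan
            i += 1
        if attempts > n_permutations:
            logger.info("rejected %d duplicate permutations",
                        attempts - n_permutations)
        return cls(G, up_size, down_size, n_permutations, ups, downs,
                   seed=seed)


def _score_from_ranks(ranks: np.ndarray, G: int, m: int) -> float:
    """Rank-only enrichment score given the 1-based ranks of set members."""
    tail = G - np.asarray(ranks, dtype=float) + 1.0
    total_tail = G * (G + 1) / 2.0
    score_in = tail.sum() / m
    score_out = (total_tail - tail.sum()) / (G - m)
    return float(score_in - score_out)


def score_units(
    matrix,
    signature: Signature,
    genes: Sequence[str],
    unit_ids: Sequence[str],
    weight_exponent: float = 0.0,
    center: bool = True,
) -> pd.DataFrame:
    """Raw up/down/combined scores for every unit.

    Signature genes absent from the universe are dropped with a
    warning; scoring fails if no signature gene is present.  For a
    one-sided signature the combined score equals the present side
    (negated for a down-only signature).
    """
    genes = list(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    up = sorted(signature.up_genes & set(genes))
    down = sorted(signature.down_genes & set(genes))
    missing = signature.genes - set(genes)
    if missing:
        logger.warning(
            "signature %s: %d genes absent from universe, dropped",
            signature.name, len(missing),
        )
    if not up and not down:
        raise ScoringError(
            f"no gene of signature {signature.name} present in the data"
        )

    m = center_matrix(matrix) if center else np.asarray(
        matrix.todense() if sp.issparse(matrix) else matrix, dtype=float
    )
    up_mask = np.zeros(len(genes), dtype=bool)
    up_mask[[gene_index[g] for g in up]] = True
    down_mask = np.zeros(len(genes), dtype=bool)
    down_mask[[gene_index[g] for g in down]] = True

    rows = []
    for j, unit in enumerate(unit_ids):
        v = m[:, j]
        up_s = ssgsea_raw_score(v, up_mask, weight_exponent) if up else 0.0
        down_s = ssgsea_raw_score(v, down_mask, weight_exponent) if down else 0.0
        if up and down:
            combined = (up_s - down_s) / 2.0
        elif up:
            combined = up_s
        else:
            combined = -down_s
        rows.append((unit, up_s, down_s, combined))
    return pd.DataFrame(
        rows, columns=["unit", "up_score", "down_score", "combined_raw"]
    ).set_index("unit")


def min_max_scale_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale combined (and part) scores to [-1000, 1000].

    Scaling is per signature per dataset, over all units.  A degenerate
    column (max == min) maps to all zeros with a warning.
    """
    out = scores.copy()
    for col, scaled_col in (
        ("combined_raw", "combined_scaled"),
        ("up_score", "up_scaled"),
        ("down_score", "down_scaled"),
    ):
        x = out[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            logger.warning("constant %s; scaled scores set to 0", col)
            out[scaled_col] = 0.0
        else:
            out[scaled_col] = -SCORE_BOUND + 2 * SCORE_BOUND * (x - lo) / (hi - lo)
    return out


def _empirical_p(null: np.ndarray, observed: float, side: str) -> float:
    """Add-one empirical p-value, one-sided."""
    n = null.size
    if side == "ge":
        exceed = int(np.count_nonzero(null >= observed))
    else:
        exceed = int(np.count_nonzero(null <= observed))
    return (exceed + 1) / (n + 1)


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: chi-square tail of -2 * sum(log p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ScoringError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, df=2 * p.size))


def permutation_significance(
    scores: pd.DataFrame,
    null: PermutationNull,
    mode: str = "st",
    n_signature_genes: Optional[int] = None,
) -> pd.DataFrame:
    """Attach p-values and significance classes to scaled scores.

    ``p_high`` combines (Fisher) the one-sided probabilities that the
    up score is as high and the down score as low as observed under
    the null; ``p_low`` mirrors it.  A unit is HIGH when ``p_high``
    passes the mode threshold and the scaled combined score exceeds
    200, LOW symmetrically below -200.  ``mode='st'`` uses a
    per-signature Bonferroni threshold 0.05 / number of signature
    genes; ``mode='bulk'`` uses 0.05.
    """
    if mode not in ("st", "bulk"):
        raise ScoringError(f"unknown mode {mode!r}")
    has_up = null.up_size > 0
    has_down = null.down_size > 0
    if n_signature_genes is None:
        n_signature_genes = null.up_size + null.down_size
    alpha = 0.05 / n_signature_genes if mode == "st" else 0.05
    if "combined_scaled" not in scores.columns:
        raise ScoringError("scores must be scaled before significance")

    out = scores.copy()
    p_up_hi = np.ones(len(out))
    p_up_lo = np.ones(len(out))
    p_dn_hi = np.ones(len(out))
    p_dn_lo = np.ones(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        if has_up:
            p_up_hi[i] = _empirical_p(null.null_up, row["up_score"], "ge")
            p_up_lo[i] = _empirical_p(null.null_up, row["up_score"], "le")
        if has_down:
            p_dn_lo[i] = _empirical_p(null.null_down, row["down_score"], "le")
            p_dn_hi[i] = _empirical_p(null.null_down, row["down_score"], "ge")

    p_high = np.empty(len(out))
    p_low = np.empty(len(out))
    for i in range(len(out)):
        if has_up and has_down:
            p_high[i] = fisher_combine([p_up_hi[i], p_dn_lo[i]])
            p_low[i] = fisher_combine([p_up_lo[i], p_dn_hi[i]])
        elif has_up:
            p_high[i], p_low[i] = p_up_hi[i], p_up_lo[i]
        else:
            p_high[i], p_low[i] = p_dn_lo[i], p_dn_hi[i]

    out["p_up"] = p_up_hi if has_up else np.nan
    out["p_down"] = p_dn_lo if has_down else np.nan
    out["p_combined_high"] = p_high
    out["p_combined_low"] = p_low
    scaled = out["combined_scaled"].to_numpy()
    cls = np.full(len(out), NOT_SIGNIFICANT, dtype=object)
    cls[(p_high <= alpha) & (scaled > SCORE_CUTOFF)] = HIGH
    cls[(p_low <= alpha) & (scaled < -SCORE_CUTOFF)] = LOW
    out["significance_class"] = cls
    return out


def score_signature(
    matrix,
    signature: Signature,
    genes: Sequence[str],
    unit_ids: Sequence[str],
    mode: str = "st",
    n_permutations: int = 1000,
    weight_exponent: float = 0.0,
    center: bool = True,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """End-to-end scoring: raw scores, scaling, permutation significance."""
    genes = list(genes)
    scores = score_units(
        matrix, signature, genes, unit_ids,
        weight_exponent=weight_exponent, center=center,
    )
    scores = min_max_scale_scores(scores)
    up_n = len(signature.up_genes & set(genes))
    down_n = len(signature.down_genes & set(genes))
    null = PermutationNull.build(
        len(genes), up_n, down_n, n_permutations=n_permutations, seed=seed,
    )
    return permutation_significance(
        scores, null, mode=mode, n_signature_genes=up_n + down_n,
    )
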