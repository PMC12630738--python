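"""Cell-count normalization, log transform, and spot/gene quality control.

Raw unique-molecule counts are normalized per spot by the number of
cells detected in that spot (``c = raw / n_cells``), which removes the
dependence of the capture on local cellularity.  For discovery
statistics the normalized counts are additionally transformed to

    ``log10(raw / n_cells * 10000 + 1)``

so that a difference of 1 on this scale corresponds to a ten-fold
change in expression for values well above the pseudocount.

Quality control keeps spots with at least 100 normalized total counts
and at least 40 detected genes, and keeps genes with a nonzero total
and at least 10 raw counts in at least 10 spots.  Both masks are
computed once on the full matrix and applied once, so applying them
again to the filtered matrix is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

SCALE = 10_000.0

#: QC defaults: minimum normalized total counts / detected genes per spot.
MIN_NORMALIZED_TOTAL = 100.0
MIN_DETECTED_GENES = 40

#: Gene filter defaults: >= MIN_COUNTS raw counts in >= MIN_SPOTS spots.
GENE_MIN_COUNTS = 10
GENE_MIN_SPOTS = 10


class PreprocessError(ValueError):
    """Raised on invalid input to normalization or QC."""


def normalize_counts(raw, n_cells):
    """Divide each spot's raw counts by its cell count.

    Parameters
    ----------
    raw : (genes, spots) array or sparse matrix of raw counts.
    n_cells : (spots,) array of per-spot cell counts, all >= 1.

    Returns
    -------
    Matrix of the same type as ``raw`` with per-cell normalized counts.
    """
    n_cells = np.asarray(n_cells, dtype=float)
    if n_cells.ndim != 1:
        raise PreprocessError("n_cells must be one-dimensional")
    if np.any(n_cells < 1):
        raise PreprocessError(
            "spots with zero cells cannot be normalized; "
            "drop them before calling normalize_counts"
        )
    if sp.issparse(raw):
        if raw.shape[1] != n_cells.size:
            raise PreprocessError("n_cells length must match spot count")
        inv = sp.diags(1.0 / n_cells)
        return (raw @ inv).tocsr()
    raw = np.asarray(raw, dtype=float)
    if raw.shape[1] != n_cells.size:
        raise PreprocessError("n_cells length must match spot count")
    return raw / n_cells[np.newaxis, :]


def log_transform(normalized):
    """Apply ``log10(c * 10000 + 1)`` elementwise.

    Zero stays zero, so sparsity is preserved; the output is dense for
    dense input and sparse (same pattern) for sparse input.
    """
    if sp.issparse(normalized):
        out = normalized.tocsr(copy=True)
        out.data = np.log10(out.data * SCALE + 1.0)
        return out
    return np.log10(np.asarray(normalized, dtype=float) * SCALE + 1.0)


def normalize_and_log(raw, n_cells):
    """Return ``(normalized, log10-transformed)`` matrices.

    Scalar inputs are supported for spot-level checks:
    ``normalize_and_log(5, 10) -> (0.5, log10(5001))``.
    """
    if np.isscalar(raw):
        if n_cells < 1:
            raise PreprocessError("n_cells must be >= 1")
        norm = raw / n_cells
        return norm, float(np.log10(norm * SCALE + 1.0))
    normalized = normalize_counts(raw, n_cells)
    return normalized, log_transform(normalized)


def _dense_or_sparse_sums(mat, axis):
    if sp.issparse(mat):
        return np.asarray(mat.sum(axis=axis)).ravel()
    return np.asarray(mat).sum(axis=axis)


def _nnz_per(mat, axis):
    if sp.issparse(mat):
        return np.asarray((mat != 0).sum(axis=axis)).ravel()
    return np.count_nonzero(np.asarray(mat), axis=axis)


def apply_spot_qc(
    normalized,
    min_total: float = MIN_NORMALIZED_TOTAL,
    min_genes: int = MIN_DETECTED_GENES,
) -> np.ndarray:
    """Boolean keep-mask over spots from normalized counts.

    A spot is kept iff its normalized total is >= ``min_total`` and the
    number of genes with normalized count > 0 is >= ``min_genes``
    (strict "less than" exclusion wording, so the boundary is kept).
    """
    if normalized.shape[0] == 0 or normalized.shape[1] == 0:
        raise PreprocessError("empty matrix")
    totals = _dense_or_sparse_sums(normalized, axis=0)
    detected = _nnz_per(normalized, axis=0)
    return (totals >= min_total) & (detected >= min_genes)


def apply_gene_filter(
    raw,
    min_counts: int = GENE_MIN_COUNTS,
    min_spots: int = GENE_MIN_SPOTS,
    mode: str = "per_spot",
) -> np.ndarray:
    """Boolean keep-mask over genes from raw counts.

    ``mode='per_spot'`` (default): gene kept iff its total is nonzero
    and at least ``min_spots`` spots each carry >= ``min_counts`` raw
    counts.  ``mode='total'``: gene kept iff nonzero in >= ``min_spots``
    spots and its total is >= ``min_counts``.
    """
    totals = _dense_or_sparse_sums(raw, axis=1)
    if mode == "per_spot":
        if sp.issparse(raw):
            big = np.asarray((raw >= min_counts).sum(axis=1)).ravel()
        else:
            big = (np.asarray(raw) >= min_counts).sum(axis=1)
        return (totals > 0) & (big >= min_spots)
    if mode == "total":
        nnz = _nnz_per(raw, axis=1)
        return (totals >= min_counts) & (nnz >= min_spots)
    raise PreprocessError(f"unknown gene filter mode {mode!r}")


@dataclass
class QCReport:
    """Per-spot totals and per-gene pass flags from one QC pass."""

    spot_totals: np.ndarray
    spot_detected: np.ndarray
    spot_keep: np.ndarray
    gene_keep: np.ndarray

    @property
    def n_spots_kept(self) -> int:
        return int(self.spot_keep.sum())

    @property
    def n_genes_kept(self) -> int:
        return int(self.gene_keep.sum())


def run_qc(raw, n_cells, **kwargs) -> QCReport:
    """Compute both masks once from the full raw matrix.

    Spot QC is evaluated on cell-count-normalized values; the gene
    filter on raw counts.  Both are derived from the unfiltered matrix,
    so the two masks commute when applied.
    """
    normalized = normalize_counts(raw, n_cells)
    spot_keep = apply_spot_qc(
        normalized,
        min_total=kwargs.get("min_total", MIN_NORMALIZED_TOTAL),
        min_genes=kwargs.get("min_genes", MIN_DETECTED_GENES),
    )
    gene_keep = apply_gene_filter(
        raw,
        min_counts=kwargs.get("gene_min_counts", GENE_MIN_COUNTS),
        min_spots=kwargs.get("gene_min_spots", GENE_MIN_SPOTS),
        mode=kwargs.get("gene_filter_mode", "per_spot"),
    )
    return QCReport(
        spot_totals=_dense_or_sparse_sums(normalized, axis=0),
        spot_detected=_nnz_per(normalized, axis=0),
        spot_keep=spot_keep,
        gene_keep=gene_keep,
    )
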