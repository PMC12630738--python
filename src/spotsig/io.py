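"""Readers and writers for the pipeline's on-disk formats.

Count data travels in a spaceranger-like bundle (``matrix.mtx`` in
MatrixMarket coordinate format plus ``features.tsv`` and
``barcodes.tsv``), metadata and result tables as tab-separated files
with header rows, gene sets as GMT.  Paired ``NAME_up`` / ``NAME_down``
GMT lines are merged into one two-sided signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .discovery import Signature

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class CountMatrix:
    """Sparse genes x spots raw counts with identifier lists."""

    matrix: sp.spmatrix
    gene_names: List[str]
    barcodes: List[str]

    def __post_init__(self) -> None:
        g, s = self.matrix.shape
        if g != len(self.gene_names):
            raise ParseError(
                f"{len(self.gene_names)} gene names for {g} matrix rows"
            )
        if s != len(self.barcodes):
            raise ParseError(
                f"{len(self.barcodes)} barcodes for {s} matrix columns"
            )

    @property
    def shape(self):
        return self.matrix.shape

    def subset(self, gene_mask=None, spot_mask=None) -> "CountMatrix":
        m = self.matrix.tocsr()
        genes = np.asarray(self.gene_names)
        barcodes = np.asarray(self.barcodes)
        if gene_mask is not None:
            m = m[gene_mask]
            genes = genes[gene_mask]
        if spot_mask is not None:
            m = m[:, spot_mask]
            barcodes = barcodes[spot_mask]
        return CountMatrix(m.tocsr(), list(genes), list(barcodes))


def write_count_bundle(directory, cm: CountMatrix) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(cm.matrix),
                     field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in cm.gene_names)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in cm.barcodes)
    )


def read_count_bundle(directory) -> CountMatrix:
    """Read a spaceranger-like MTX bundle.

    Raises :class:`ParseError` on missing files, malformed MTX content
    or identifier/dimension mismatches.
    """
    directory = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / name).exists():
            raise ParseError(f"missing {name} in {directory}")
    try:
        matrix = scipy.io.mmread(directory / "matrix.mtx")
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise ParseError(f"malformed matrix.mtx in {directory}: {exc}")
    genes = (directory / "features.tsv").read_text().splitlines()
    genes = [line.split("\t")[0] for line in genes if line]
    barcodes = [
        line.split("\t")[0]
        for line in (directory / "barcodes.tsv").read_text().splitlines()
        if line
    ]
    if (matrix < 0).nnz if sp.issparse(matrix) else (matrix < 0).any():
        raise ParseError("negative counts in matrix.mtx")
    return CountMatrix(sp.csr_matrix(matrix), genes, barcodes)


def write_spots_table(path, spots: pd.DataFrame) -> None:
    spots.to_csv(path, sep="\t", index=True, index_label="barcode")


def read_spots_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_tsv(path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# GMT

def write_gmt(path, signatures: Sequence[Signature]) -> None:
    """Write each signature as paired NAME_up / NAME_down lines."""
    lines = []
    for sig in signatures:
        if sig.up_genes:
            lines.append("\t".join([f"{sig.name}_up", "up-regulated part"]
                                   + sorted(sig.up_genes)))
        if sig.down_genes:
            lines.append("\t".join([f"{sig.name}_down",
                                    "down-regulated part"]
                                   + sorted(sig.down_genes)))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_gmt(path) -> List[Signature]:
    """Read GMT lines, merging NAME_up / NAME_down pairs.

    Duplicate genes within a line are deduplicated with a warning;
    empty lines are skipped.  Unpaired lines become one-sided
    signatures.
    """
    entries: Dict[str, Dict[str, set]] = {}
    order: List[str] = []
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs name, description and "
                "at least one gene"
            )
        name, _desc, genes = parts[0], parts[1], parts[2:]
        if len(set(genes)) < len(genes):
            logger.warning("%s:%d: duplicate genes deduplicated",
                           path, lineno)
        gene_set = set(genes)
        if name.endswith("_up"):
            base, side = name[:-3], "up"
        elif name.endswith("_down"):
            base, side = name[:-5], "down"
        else:
            base, side = name, "up"
        if base not in entries:
            entries[base] = {"up": set(), "down": set()}
            order.append(base)
        entries[base][side] |= gene_set
    return [
        Signature(name, up_genes=entries[name]["up"],
                  down_genes=entries[name]["down"])
        for name in order
    ]


def write_config(path, config: dict) -> None:
    """Serialize a flat config dict as YAML-style key/value lines."""
    import yaml

    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    import yaml

    return yaml.safe_load(Path(path).read_text())
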