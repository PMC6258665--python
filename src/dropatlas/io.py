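"""Reading and writing digital gene expression (DGE) matrices.

The universal substrate of the pipeline is the genes x barcodes integer
count matrix produced by droplet scRNA-seq pre-processing (the Drop-seq
``DigitalExpression`` dialect: tab-separated, a ``GENE`` column followed
by one column per cell barcode).  An MTX triplet representation
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) is supported as an
interchangeable alternative.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DGEFormatError(ValueError):
    """Raised when a DGE/MTX file violates the format contract."""


@dataclass
class CountMatrix:
    """Integer gene x barcode expression counts with identifiers.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    barcodes
        Unique cell-barcode strings, one per matrix column.
    counts
        Non-negative integer array of shape ``(len(gene_ids), len(barcodes))``.
    """

    gene_ids: list[str]
    barcodes: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise DGEFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise DGEFormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise DGEFormatError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DGEFormatError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise DGEFormatError("duplicate barcodes")
        self.counts = counts

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def library_sizes(self) -> np.ndarray:
        """Total counts per barcode (column sums)."""
        return self.counts.sum(axis=0)

    def genes_detected_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 per barcode."""
        return (self.counts > 0).sum(axis=0)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene id not in matrix: {gene_id!r}") from None

    def subset_cells(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            barcodes=[self.barcodes[i] for i in keep],
            counts=self.counts[:, keep].copy(),
        )

    def subset_genes(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            barcodes=list(self.barcodes),
            counts=self.counts[keep, :].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.barcodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.barcodes == other.barcodes
            and np.array_equal(self.counts, other.counts)
        )


def read_dge(path: str | Path) -> CountMatrix:
    """Read a Drop-seq style DGE TSV (optionally gzipped).

    The expected layout is a header row of barcodes preceded by a gene-id
    column header (conventionally ``GENE``), then one row per gene with
    integer counts.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise DGEFormatError(f"{path}: duplicate barcodes in header")
        fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    barcodes = header
    gene_ids = [str(g) for g in df.index]
    if len(set(barcodes)) != len(barcodes):
        raise DGEFormatError(f"{path}: duplicate barcodes in header")
    if len(set(gene_ids)) != len(gene_ids):
        raise DGEFormatError(f"{path}: duplicate gene ids")
    values = np.empty((len(gene_ids), len(barcodes)), dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise DGEFormatError(
                f"{path}: non-integer count in column {col!r}, "
                f"row(s) {list(bad[:3])}"
            ) from None
    float_check = df.astype(float).to_numpy()
    if not np.array_equal(float_check, values):
        rows, cols = np.nonzero(float_check != values)
        raise DGEFormatError(
            f"{path}: non-integer count at gene {gene_ids[rows[0]]!r}, "
            f"barcode {barcodes[cols[0]]!r}"
        )
    return CountMatrix(gene_ids=gene_ids, barcodes=barcodes, counts=values)


def write_dge(matrix: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as a Drop-seq DGE TSV (gzipped if path ends .gz)."""
    path = Path(path)
    df = matrix.to_dataframe()
    df.index.name = "GENE"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t")


def read_mtx(directory: str | Path) -> CountMatrix:
    """Read an MTX triplet (matrix.mtx, genes.tsv, barcodes.tsv) directory."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    genes = (directory / "genes.tsv").read_text().splitlines()
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    if not np.allclose(counts, np.round(counts)):
        raise DGEFormatError(f"{directory}: MTX matrix contains non-integer values")
    return CountMatrix(gene_ids=genes, barcodes=barcodes, counts=counts.astype(np.int64))


def write_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as MTX + genes.tsv + barcodes.tsv sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.counts)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse, field="integer")
    (directory / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(matrix.barcodes) + "\n")
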