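"""Cell calling and quality control for DGE matrices.

Cell calling follows the knee-plot convention: barcodes are ranked by
total reads, the cumulative fraction of reads is plotted against rank,
and the knee — the rank at maximum perpendicular distance from the
chord joining the curve's endpoints — separates real cells from the
ambient barcode tail.

QC filtering keeps cells detecting between ``min_genes`` and
``max_genes`` genes (inclusive at both bounds) and then genes detected
in at least ``min_cells`` remaining cells.  Normalization scales each
cell to ``scale_factor`` total counts and applies log1p (natural log).
Cells dominated by a gene signature (by default ribosomal protein
genes) can be excluded by the fraction of their library the signature
occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

#: common ribosomal protein gene prefixes (fly Rp genes and the
#: capitalised vertebrate-style RPL/RPS spellings)
RIBOSOMAL_PREFIXES = ("RpL", "RpS", "RPL", "RPS", "mRpL", "mRpS")


class DegenerateCurveError(ValueError):
    """Raised when a barcode-rank curve has no knee (e.g. all-equal counts)."""


class EmptyMatrixError(ValueError):
    """Raised when a QC filter removes every cell or gene."""


@dataclass
class KneeResult:
    """Outcome of knee-plot cell calling."""

    n_cells_selected: int
    read_threshold: int
    rank_curve: np.ndarray = field(repr=False)  # read counts, descending


@dataclass
class NormalizedMatrix:
    """Log-normalized expression on the same gene x cell grid.

    values are ``log(1 + count / cell_total * scale_factor)`` so that
    ``sum(exp(value) - 1)`` over any cell recovers ``scale_factor``.
    """

    gene_ids: list[str]
    barcodes: list[str]
    values: np.ndarray = field(repr=False)
    scale_factor: float = 1e4
    log_base: str = "e"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.barcodes)


def knee_call(read_counts_per_barcode) -> KneeResult:
    """Select real cells from the reads-per-barcode distribution.

    Barcodes are sorted by reads descending; the cumulative fraction of
    reads is traced against rank and the knee is the rank maximizing
    the perpendicular distance to the straight line joining the curve's
    endpoints (ties broken toward the smaller rank).  All barcodes at
    rank <= knee are selected.
    """
    reads = np.asarray(read_counts_per_barcode, dtype=float)
    reads = reads[reads > 0]
    if reads.size < 10:
        raise ValueError("need at least 10 barcodes with positive read counts")
    order = np.sort(reads)[::-1]
    cum = np.cumsum(order) / order.sum()
    ranks = np.arange(1, order.size + 1, dtype=float)

    # perpendicular distance from each curve point to the endpoint chord
    x1, y1 = ranks[0], cum[0]
    x2, y2 = ranks[-1], cum[-1]
    chord_len = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ranks - (x2 - x1) * cum + x2 * y1 - y2 * x1) / chord_len
    if dist.max() <= 1e-9:
        raise DegenerateCurveError(
            "cumulative read curve is a straight line (all counts equal?); "
            "no knee to select"
        )
    knee = int(np.argmax(dist))  # argmax returns the first (smallest) rank on ties
    n_selected = knee + 1
    return KneeResult(
        n_cells_selected=n_selected,
        read_threshold=int(order[knee]),
        rank_curve=order.astype(np.int64),
    )


def filter_cells_genes(
    matrix: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 3000,
    min_cells: int = 3,
) -> CountMatrix:
    """Apply gene-per-cell and cell-per-gene QC filters.

    Cells are kept iff the number of genes they detect (count > 0) lies
    in [min_genes, max_genes], both bounds inclusive; genes are then
    kept iff detected in at least ``min_cells`` of the remaining cells.
    Original ordering is preserved.
    """
    genes_per_cell = matrix.genes_detected_per_cell()
    keep_cells = (genes_per_cell >= min_genes) & (genes_per_cell <= max_genes)
    if not keep_cells.any():
        raise EmptyMatrixError(
            f"gene-per-cell filter [{min_genes}, {max_genes}] removed every cell"
        )
    sub = matrix.subset_cells(keep_cells)
    cells_per_gene = (sub.counts > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells
    if not keep_genes.any():
        raise EmptyMatrixError(
            f"min_cells={min_cells} filter removed every gene"
        )
    return sub.subset_genes(keep_genes)


def normalize(matrix: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Scale each cell to ``scale_factor`` total counts and log1p.

    value = log(1 + count / cell_total * scale_factor), natural log.
    Run after filtering; an all-zero cell is an error.
    """
    totals = matrix.library_sizes().astype(float)
    zero = totals == 0
    if zero.any():
        bad = [matrix.barcodes[i] for i in np.flatnonzero(zero)[:5]]
        raise ValueError(f"cannot normalize all-zero cell(s): {bad}")
    values = np.log1p(matrix.counts / totals[None, :] * scale_factor)
    return NormalizedMatrix(
        gene_ids=list(matrix.gene_ids),
        barcodes=list(matrix.barcodes),
        values=values,
        scale_factor=scale_factor,
        log_base="e",
    )


def denormalize(norm: NormalizedMatrix, cell_totals) -> np.ndarray:
    """Invert :func:`normalize` given the original cell totals."""
    totals = np.asarray(cell_totals, dtype=float)
    raw = np.expm1(norm.values) / norm.scale_factor * totals[None, :]
    return np.rint(raw).astype(np.int64)


def exclude_signature_cells(
    matrix: CountMatrix,
    gene_prefixes=RIBOSOMAL_PREFIXES,
    fraction_threshold: float = 0.4,
) -> list[str]:
    """Barcodes whose library is dominated by a gene signature.

    A barcode is excluded iff the summed counts of genes whose id starts
    with any of ``gene_prefixes`` exceed ``fraction_threshold`` of its
    library.  The excluded barcodes are returned (reported, never
    silently dropped).
    """
    prefixes = tuple(gene_prefixes)
    if not prefixes:
        raise ValueError("gene_prefixes must be non-empty")
    mask = np.array(
        [g.startswith(prefixes) for g in matrix.gene_ids], dtype=bool
    )
    sig = matrix.counts[mask, :].sum(axis=0)
    totals = matrix.library_sizes()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, sig / np.maximum(totals, 1), 0.0)
    excluded = frac > fraction_threshold
    return [matrix.barcodes[i] for i in np.flatnonzero(excluded)]


def qc_report(
    matrix: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 3000,
    signature_prefixes=RIBOSOMAL_PREFIXES,
    signature_threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-barcode QC table: n_genes, n_reads, kept flag and reason."""
    genes_per_cell = matrix.genes_detected_per_cell()
    reads = matrix.library_sizes()
    excluded_sig = set(
        exclude_signature_cells(matrix, signature_prefixes, signature_threshold)
    )
    reasons = []
    for i, bc in enumerate(matrix.barcodes):
        if genes_per_cell[i] < min_genes:
            reasons.append("too_few_genes")
        elif genes_per_cell[i] > max_genes:
            reasons.append("too_many_genes")
        elif bc in excluded_sig:
            reasons.append("signature_dominated")
        else:
            reasons.append("")
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "n_genes": genes_per_cell,
            "n_reads": reads,
            "kept": [r == "" for r in reasons],
            "reason": reasons,
        }
    ).set_index("barcode")
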