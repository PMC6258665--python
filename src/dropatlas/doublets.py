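"""Doublet assessment from mutually exclusive marker co-expression.

In droplet scRNA-seq, markers of distinct cell subtypes that are never
co-expressed in single cells (e.g. the photoreceptor-subtype markers
sens for R8, ro for R2/5 and B-H2 for R1/6) can only appear together in
a library that captured two cells.  Library purity is therefore
quantified by cross-classifying cells as positive/negative for each
marker of a pair, comparing the observed double-positive fraction with
the expectation under independent expression, and testing the 2x2
table with a chi-square statistic.

A low observed co-expression relative to the independence expectation
indicates that libraries are predominantly single cells; the residual
double-positive fraction, under an additive two-cell library model,
identifies the doublet rate itself (:func:`estimate_doublet_rate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix


class UndefinedStatisticError(ValueError):
    """A chi-square statistic is undefined (an expected cell is zero)."""

    def __init__(self, message: str, exp_frac: float):
        super().__init__(message)
        self.exp_frac = exp_frac


@dataclass(frozen=True)
class MarkerPair:
    """Two markers expected to be mutually exclusive in single cells."""

    gene_a: str
    gene_b: str
    label: str = ""

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("marker pair genes must differ")


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-classification of cells by detection of two markers."""

    n_ab: int        # positive for both
    n_a_only: int
    n_b_only: int
    n_neither: int

    @property
    def n(self) -> int:
        return self.n_ab + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def n_a(self) -> int:
        """Marginal count positive for A (single-positive inclusive)."""
        return self.n_ab + self.n_a_only

    @property
    def n_b(self) -> int:
        return self.n_ab + self.n_b_only

    def as_array(self) -> np.ndarray:
        """2x2 layout: rows = A status, columns = B status."""
        return np.array(
            [[self.n_ab, self.n_a_only], [self.n_b_only, self.n_neither]]
        )


@dataclass
class CoexpressionResult:
    """Observed vs independence-expected co-expression of a marker pair."""

    pair: MarkerPair | None
    n: int
    n_a: int
    n_b: int
    n_ab: int
    obs_frac: float
    exp_frac: float
    chi2: float
    df: int
    p: float
    direction: int  # sign of (observed - expected)


def coexpression_table(
    matrix: CountMatrix,
    cells,
    pair: MarkerPair,
    detect_threshold: int = 1,
) -> ContingencyTable:
    """Cross-classify a cell subset by detection of the two markers.

    A cell is positive for a gene iff its raw count is at least
    ``detect_threshold`` (default 1: transcript presence).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("cell subset is empty")
    col_idx = {bc: j for j, bc in enumerate(matrix.barcodes)}
    missing = [bc for bc in cells if bc not in col_idx]
    if missing:
        raise KeyError(f"barcodes not in matrix: {missing[:3]}")
    cols = np.array([col_idx[bc] for bc in cells])
    ia = matrix.gene_index(pair.gene_a)
    ib = matrix.gene_index(pair.gene_b)
    a_pos = matrix.counts[ia, cols] >= detect_threshold
    b_pos = matrix.counts[ib, cols] >= detect_threshold
    return ContingencyTable(
        n_ab=int(np.sum(a_pos & b_pos)),
        n_a_only=int(np.sum(a_pos & ~b_pos)),
        n_b_only=int(np.sum(~a_pos & b_pos)),
        n_neither=int(np.sum(~a_pos & ~b_pos)),
    )


def independence_test(
    table: ContingencyTable,
    pair: MarkerPair | None = None,
    correction: bool = False,
) -> CoexpressionResult:
    """Chi-square test of the 2x2 table against marginal independence.

    Expected cell counts come from the marginals
    (row_total x col_total / n); the statistic sums
    (obs - exp)^2 / exp over the four cells with no continuity
    correction by default, df = 1, two-sided p from the chi-square
    distribution.  The direction of the departure (observed double
    positives above or below expectation) is reported separately.
    """
    n = table.n
    if n < 1:
        raise ValueError("empty table")
    obs_frac = table.n_ab / n
    exp_frac = (table.n_a / n) * (table.n_b / n)
    # rows = A status, columns = B status
    obs = np.array(
        [
            [table.n_ab, table.n_a_only],
            [table.n_b_only, table.n_neither],
        ],
        dtype=float,
    )
    row = np.array([table.n_a, n - table.n_a], dtype=float)
    col = np.array([table.n_b, n - table.n_b], dtype=float)
    exp = np.outer(row, col) / n
    if np.any(exp == 0):
        raise UndefinedStatisticError(
            "an expected cell count is zero; chi-square undefined",
            exp_frac=exp_frac,
        )
    diff = np.abs(obs - exp)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / exp))
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return CoexpressionResult(
        pair=pair,
        n=n,
        n_a=table.n_a,
        n_b=table.n_b,
        n_ab=table.n_ab,
        obs_frac=obs_frac,
        exp_frac=exp_frac,
        chi2=chi2,
        df=1,
        p=p,
        direction=int(np.sign(obs_frac - exp_frac)),
    )


def combined_test(results: list[CoexpressionResult]) -> tuple[float, int, float]:
    """Combine independent 1-df chi-square statistics by summation.

    Returns (chi2_total, df_total, p) with p from the chi-square
    distribution at the summed degrees of freedom (Fisher-style
    combination of independent statistics).
    """
    results = [r for r in results if r.chi2 is not None]
    if not results:
        raise ValueError("no results with a defined chi-square statistic")
    chi2_total = float(sum(r.chi2 for r in results))
    df_total = int(sum(r.df for r in results))
    p = float(scipy.stats.chi2.sf(chi2_total, df=df_total))
    return chi2_total, df_total, p


def singlet_purity(results: list[CoexpressionResult]) -> float:
    """1 - max observed co-expression fraction over the marker pairs.

    The complement of the worst mixed-marker fraction: a conservative
    lower bound on the fraction of libraries consistent with a single
    cell.
    """
    if not results:
        raise ValueError("no co-expression results")
    return 1.0 - max(r.obs_frac for r in results)


def estimate_doublet_rate_from_fractions(
    frac_a: float,
    frac_b: float,
    frac_ab: float,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> float:
    """Doublet rate from the co-expression of a mutually exclusive pair.

    Under an additive two-cell library model with markers that single
    cells never co-express, the observed fractions satisfy

        P(A+)  = alpha * (1 + d * (1 - alpha))
        P(B+)  = beta  * (1 + d * (1 - beta))
        P(A+B+) = 2 * d * alpha * beta

    where alpha, beta are the single-cell positive rates and d the
    doublet fraction.  The system is solved by fixed-point iteration;
    the naive estimate ``frac_ab / (2 * frac_a * frac_b)`` is its first
    step.
    """
    if frac_a <= 0 or frac_b <= 0:
        raise ValueError("marginal positive fractions must be positive")
    alpha, beta, d = frac_a, frac_b, 0.0
    for _ in range(max_iter):
        d_new = frac_ab / (2 * alpha * beta)
        alpha_new = frac_a / (1 + d_new * (1 - alpha))
        beta_new = frac_b / (1 + d_new * (1 - beta))
        if (
            abs(d_new - d) < tol
            and abs(alpha_new - alpha) < tol
            and abs(beta_new - beta) < tol
        ):
            alpha, beta, d = alpha_new, beta_new, d_new
            break
        alpha, beta, d = alpha_new, beta_new, d_new
    return float(d)


def estimate_doublet_rate(
    matrix: CountMatrix,
    cells,
    pair: MarkerPair,
    detect_threshold: int = 1,
) -> float:
    """Doublet rate of a cell subset from one mutually exclusive pair."""
    table = coexpression_table(matrix, cells, pair, detect_threshold)
    return estimate_doublet_rate_from_fractions(
        table.n_a / table.n, table.n_b / table.n, table.n_ab / table.n
    )


def read_marker_pairs(path) -> list[MarkerPair]:
    """Read marker pairs from a TSV with columns gene_a, gene_b, label."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker pair table needs columns {sorted(required)}")
    return [
        MarkerPair(
            gene_a=row["gene_a"],
            gene_b=row["gene_b"],
            label=str(row.get("label", "")) if "label" in df.columns else "",
        )
        for _, row in df.iterrows()
    ]


def results_table(results: list[CoexpressionResult]) -> pd.DataFrame:
    """Tidy per-pair report of the co-expression assessment."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.pair.label if r.pair else "",
                "gene_a": r.pair.gene_a if r.pair else "",
                "gene_b": r.pair.gene_b if r.pair else "",
                "n": r.n,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "n_ab": r.n_ab,
                "obs_frac": r.obs_frac,
                "exp_frac": r.exp_frac,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
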