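"""Synthetic droplet scRNA-seq count matrices with planted ground truth.

The generator emulates the statistical structure a droplet scRNA-seq
atlas analysis assumes: a mixture of cell types at uneven proportions
(including a rare type near 0.5% of cells), type-specific marker genes
that are over-expressed by a configurable fold, optionally mutually
exclusive markers (silenced outside the types that carry them), two
genotypes sharing all populations except one genotype-restricted
population, replicates contributing evenly to every type, doublets
formed by summing two singlet libraries, and an ambient low-read
barcode tail for knee-plot cell calling.

Counts are drawn per gene and cell from a negative binomial
(gamma-Poisson) distribution with

    mean = baseline_gene_mean * marker_fold * library_size_factor

and a single global dispersion.  Baseline gene means are log-normal,
library-size factors per cell are log-normal, so the matrix shows the
over-dispersion and dropout familiar from real DGE data.  All
randomness flows from one integer seed; identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CountMatrix


class SimConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


class SimulationWarning(UserWarning):
    """Non-fatal simulation events (e.g. a configured type drew no cells)."""


@dataclass
class CellType:
    """One planted population.

    markers are (gene_index, fold) pairs: the gene's baseline mean is
    multiplied by ``fold`` in cells of this type.  A genotype_restriction
    confines the population to one genotype label.
    """

    name: str
    proportion: float
    markers: list[tuple[int, float]] = field(default_factory=list)
    genotype_restriction: str | None = None


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    Parameters
    ----------
    n_cells, n_genes
        Matrix dimensions before doublet/ambient additions.
    cell_types
        Planted populations; proportions must sum to 1.
    genotype_fractions
        Mapping genotype label -> fraction of cells; must sum to 1.
    n_replicates
        Biological replicates, assigned uniformly at random.
    doublet_rate
        Fraction of barcodes replaced by two-cell libraries, in [0, 0.5].
    library_size_log_mean, library_size_log_sd
        Log-scale parameters of the per-cell library-size factor.
    nb_dispersion
        Gamma shape of the gamma-Poisson mixture (smaller = noisier).
    ambient_n_barcodes, ambient_read_scale
        Extra empty-droplet barcodes whose library sizes are
        ``ambient_read_scale`` times the median real-cell library.
    exclusive_genes
        Gene indices silenced (mean zero) in every cell whose type does
        not list them as a marker — models mutually exclusive markers.
    marker_baseline_mean
        If set, overrides the random baseline mean of every marker gene
        so marker detectability does not depend on the luck of the
        baseline draw.
    replicate_scale
        Optional per-replicate library scaling factors (batch effect);
        default None = no batch effect.
    """

    n_cells: int = 6000
    n_genes: int = 2000
    cell_types: list[CellType] = field(default_factory=list)
    genotype_fractions: dict[str, float] = field(
        default_factory=lambda: {"wild_type": 1.0}
    )
    n_replicates: int = 1
    doublet_rate: float = 0.0
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 1.0
    baseline_log_mean: float = float(np.log(0.25))
    baseline_log_sd: float = 1.2
    ambient_n_barcodes: int = 0
    ambient_read_scale: float = 0.03
    exclusive_genes: list[int] = field(default_factory=list)
    marker_baseline_mean: float | None = 0.3
    replicate_scale: list[float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise SimConfigError("at least one cell type required")
        total = sum(t.proportion for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"cell type proportions sum to {total}, not 1")
        gtotal = sum(self.genotype_fractions.values())
        if abs(gtotal - 1.0) > 1e-9:
            raise SimConfigError(f"genotype fractions sum to {gtotal}, not 1")
        if not 0.0 <= self.doublet_rate <= 0.5:
            raise SimConfigError(f"doublet_rate {self.doublet_rate} outside [0, 0.5]")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be positive")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise SimConfigError("cell type names must be unique")
        for t in self.cell_types:
            for gene, fold in t.markers:
                if not 0 <= gene < self.n_genes:
                    raise SimConfigError(
                        f"marker gene index {gene} of type {t.name!r} "
                        f"outside 0..{self.n_genes - 1}"
                    )
                if fold < 1:
                    raise SimConfigError(
                        f"marker fold {fold} of type {t.name!r} below 1"
                    )
            if (
                t.genotype_restriction is not None
                and t.genotype_restriction not in self.genotype_fractions
            ):
                raise SimConfigError(
                    f"type {t.name!r} restricted to unknown genotype "
                    f"{t.genotype_restriction!r}"
                )
        for gene in self.exclusive_genes:
            if not 0 <= gene < self.n_genes:
                raise SimConfigError(f"exclusive gene index {gene} out of range")
        if self.ambient_n_barcodes and not 0.0 < self.ambient_read_scale < 0.5:
            raise SimConfigError("ambient_read_scale must lie in (0, 0.5)")
        if self.replicate_scale is not None and len(self.replicate_scale) != self.n_replicates:
            raise SimConfigError("replicate_scale length must equal n_replicates")

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = [
            {
                "name": t.name,
                "proportion": t.proportion,
                "markers": [[int(g), float(f)] for g, f in t.markers],
                "genotype_restriction": t.genotype_restriction,
            }
            for t in self.cell_types
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["cell_types"] = [
            CellType(
                name=t["name"],
                proportion=t["proportion"],
                markers=[(int(g), float(f)) for g, f in t.get("markers", [])],
                genotype_restriction=t.get("genotype_restriction"),
            )
            for t in d.get("cell_types", [])
        ]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def default_config(**overrides) -> SimConfig:
    """Atlas-like default configuration.

    Fifteen populations at uneven proportions (one rare type at 0.5% of
    cells), three marker genes per type at fold 20, two extra mutually
    exclusive photoreceptor-subtype markers at fold 40, eleven
    replicates, two genotypes at equal fractions with one population
    restricted to the mutant genotype, 3% doublets and an ambient
    barcode tail.
    """
    proportions = {
        "UND": 0.16, "PPN": 0.12, "MF": 0.06, "INT": 0.14, "SMW": 0.05,
        "EPR": 0.10, "LPR": 0.09, "PG": 0.04, "WG": 0.03, "DPE": 0.07,
        "VPE": 0.06, "EAB": 0.04, "OCx": 0.02, "HEMO": 0.005, "MET": 0.015,
    }
    types = []
    for i, (name, prop) in enumerate(proportions.items()):
        markers = [(3 * i + j, 20.0) for j in range(3)]
        types.append(
            CellType(
                name=name,
                proportion=prop,
                markers=markers,
                genotype_restriction="mutant" if name == "MET" else None,
            )
        )
    # mutually exclusive photoreceptor-subtype markers (sens/ro style):
    # silenced outside their type, strongly expressed within it
    n_shared = 3 * len(types)
    for t in types:
        if t.name == "EPR":
            t.markers = t.markers + [(n_shared, 40.0)]
        if t.name == "LPR":
            t.markers = t.markers + [(n_shared + 1, 40.0)]
    cfg = SimConfig(
        cell_types=types,
        genotype_fractions={"wild_type": 0.5, "mutant": 0.5},
        n_replicates=11,
        doublet_rate=0.03,
        ambient_n_barcodes=3000,
        exclusive_genes=[n_shared, n_shared + 1],
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def exclusive_pair_config(
    n_cells: int = 5000,
    n_genes: int = 300,
    doublet_rate: float = 0.0,
    p_a: float = 0.30,
    p_b: float = 0.30,
    fold: float = 40.0,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Two populations carrying one mutually exclusive marker each.

    The minimal configuration for doublet co-expression studies: type A
    cells express gene ``g_excl_a``, type B cells express ``g_excl_b``,
    and neither gene is expressed anywhere else, so any double-positive
    library is a doublet (up to detection noise).
    """
    types = [
        CellType("typeA", p_a, markers=[(0, fold)]),
        CellType("typeB", p_b, markers=[(1, fold)]),
        CellType("filler", 1.0 - p_a - p_b, markers=[]),
    ]
    cfg = SimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        cell_types=types,
        doublet_rate=doublet_rate,
        exclusive_genes=[0, 1],
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def null_pair_config(
    n_cells: int = 5000,
    n_genes: int = 20,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A single homogeneous population with two independent genes.

    With a constant library-size factor and independent per-gene
    negative binomial draws, the detection events of the two genes are
    exactly independent across cells — the null regime in which a 2x2
    independence test should be calibrated (uniform p-values).
    """
    cfg = SimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        cell_types=[CellType("cells", 1.0, markers=[(0, 1.0), (1, 1.0)])],
        library_size_log_sd=0.0,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _barcode_names(n: int, prefix: str = "CELL") -> list[str]:
    return [f"{prefix}_{i:05d}" for i in range(n)]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a synthetic DGE matrix and its ground-truth metadata.

    Returns the counts (genes x barcodes) and a truth table indexed by
    barcode with columns cell_type, genotype, replicate, is_doublet,
    doublet_components and is_ambient.  Doublets and ambient barcodes
    are added according to the config (rates may be zero).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes

    # baseline gene means, optionally pinned for marker genes
    means = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=g)
    marker_genes = sorted({gi for t in config.cell_types for gi, _ in t.markers})
    if config.marker_baseline_mean is not None:
        means[marker_genes] = config.marker_baseline_mean

    # type assignment (multinomial by proportion)
    props = np.array([t.proportion for t in config.cell_types])
    type_idx = rng.choice(len(config.cell_types), size=n, p=props)
    for i, t in enumerate(config.cell_types):
        if not np.any(type_idx == i):
            warnings.warn(
                f"configured type {t.name!r} drew zero cells at n={n}",
                SimulationWarning,
                stacklevel=2,
            )

    # genotype: restricted types get their genotype, others draw by fraction
    genotypes = np.array(list(config.genotype_fractions))
    gfrac = np.array([config.genotype_fractions[k] for k in genotypes])
    geno = genotypes[rng.choice(len(genotypes), size=n, p=gfrac)]
    for i, t in enumerate(config.cell_types):
        if t.genotype_restriction is not None:
            geno[type_idx == i] = t.genotype_restriction

    replicate = rng.integers(1, config.n_replicates + 1, size=n)
    lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=n)
    if config.replicate_scale is not None:
        lib = lib * np.asarray(config.replicate_scale)[replicate - 1]

    # per-cell mean matrix: baseline x marker fold x library factor
    mean_mat = np.tile(means[:, None], (1, n))
    excl = np.asarray(sorted(config.exclusive_genes), dtype=int)
    if excl.size:
        mean_mat[excl, :] = 0.0
    for i, t in enumerate(config.cell_types):
        cells = type_idx == i
        if not np.any(cells):
            continue
        for gi, fold in t.markers:
            base = means[gi]
            mean_mat[gi, cells] = base * fold
    mean_mat *= lib[None, :]

    # gamma-Poisson = negative binomial with mean m, dispersion theta
    theta = config.nb_dispersion
    lam = np.zeros_like(mean_mat)
    pos = mean_mat > 0
    lam[pos] = rng.gamma(theta, mean_mat[pos] / theta)
    counts = rng.poisson(lam).astype(np.int64)

    type_names = np.array([t.name for t in config.cell_types])
    truth = pd.DataFrame(
        {
            "cell_type": type_names[type_idx],
            "genotype": geno,
            "replicate": replicate,
            "is_doublet": False,
            "doublet_components": pd.Series([None] * n, dtype=object),
            "is_ambient": False,
        },
        index=pd.Index(_barcode_names(n), name="barcode"),
    )
    matrix = CountMatrix(
        gene_ids=_gene_names(g), barcodes=list(truth.index), counts=counts
    )

    if config.doublet_rate > 0:
        matrix, truth = inject_doublets(
            matrix, truth, config.doublet_rate, seed=int(rng.integers(2**31))
        )
    if config.ambient_n_barcodes > 0:
        matrix, truth = add_ambient_barcodes(
            matrix,
            config.ambient_n_barcodes,
            config.ambient_read_scale,
            seed=int(rng.integers(2**31)),
            truth=truth,
        )
    return matrix, truth


def inject_doublets(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    rate: float,
    seed: int,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Replace a fraction of barcodes with sums of two singlet libraries.

    ``round(rate * n_cells)`` barcodes are overwritten by the
    element-wise sum of two distinct randomly chosen singlet columns
    (the two components of each doublet are drawn without replacement;
    component libraries are added with no downsampling).  The truth
    table records the component types.
    """
    if not 0.0 <= rate <= 0.5:
        raise SimConfigError(f"doublet rate {rate} outside [0, 0.5]")
    n = matrix.n_cells
    n_doublets = int(round(rate * n))
    if n_doublets == 0:
        return matrix, truth
    rng = np.random.default_rng(seed)
    replaced = rng.choice(n, size=n_doublets, replace=False)
    pool = np.setdiff1d(np.arange(n), replaced)
    # independent component pairs; resample the few same-same collisions
    c1 = rng.choice(pool, size=n_doublets)
    c2 = rng.choice(pool, size=n_doublets)
    while np.any(c1 == c2):
        clash = c1 == c2
        c2[clash] = rng.choice(pool, size=int(clash.sum()))
    counts = matrix.counts.copy()
    counts[:, replaced] = matrix.counts[:, c1] + matrix.counts[:, c2]
    truth = truth.copy()
    types = truth["cell_type"].to_numpy()
    t1, t2 = types[c1], types[c2]
    components = np.array(
        ["+".join(sorted(pair)) for pair in zip(t1, t2)], dtype=object
    )
    truth.iloc[replaced, truth.columns.get_loc("cell_type")] = t1
    truth.iloc[replaced, truth.columns.get_loc("is_doublet")] = True
    truth.iloc[replaced, truth.columns.get_loc("doublet_components")] = components
    truth.iloc[replaced, truth.columns.get_loc("genotype")] = (
        truth["genotype"].to_numpy()[c1]
    )
    return (
        CountMatrix(matrix.gene_ids, matrix.barcodes, counts),
        truth,
    )


def add_ambient_barcodes(
    matrix: CountMatrix,
    n: int,
    scale: float,
    seed: int,
    truth: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Append empty-droplet barcodes with small libraries of pooled RNA.

    Each ambient barcode draws a library size around ``scale`` times the
    median real-cell library and distributes it over genes according to
    the pooled gene frequency of the real cells — the low-read tail a
    knee plot is meant to cut away.
    """
    if n < 0:
        raise SimConfigError("ambient barcode count must be non-negative")
    if n == 0:
        return matrix, truth
    if not 0.0 < scale < 0.5:
        raise SimConfigError(f"ambient_read_scale {scale} outside (0, 0.5)")
    rng = np.random.default_rng(seed)
    pooled = matrix.counts.sum(axis=1).astype(float)
    if pooled.sum() == 0:
        raise SimConfigError("cannot draw ambient profile from an all-zero matrix")
    probs = pooled / pooled.sum()
    target = scale * float(np.median(matrix.library_sizes()))
    libs = np.maximum(rng.poisson(target, size=n), 1)
    ambient = np.column_stack(
        [rng.multinomial(int(l), probs) for l in libs]
    ).astype(np.int64)
    new_barcodes = matrix.barcodes + _barcode_names(n, prefix="AMBIENT")
    new_counts = np.concatenate([matrix.counts, ambient], axis=1)
    out = CountMatrix(matrix.gene_ids, new_barcodes, new_counts)
    if truth is not None:
        amb_truth = pd.DataFrame(
            {
                "cell_type": "ambient",
                "genotype": "ambient",
                "replicate": 0,
                "is_doublet": False,
                "doublet_components": pd.Series([None] * n, dtype=object),
                "is_ambient": True,
            },
            index=pd.Index(_barcode_names(n, prefix="AMBIENT"), name="barcode"),
        )
        truth = pd.concat([truth, amb_truth])
    return out, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    df["doublet_components"] = df["doublet_components"].where(
        df["doublet_components"].notna(), None
    )
    return df
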