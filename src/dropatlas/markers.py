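"""Marker statistics and cluster annotation.

Given a log-normalized matrix and a cluster labeling (an input: graph
clustering itself is upstream of this package), this module computes
dot-plot statistics (fraction of expressing cells and scaled mean
expression per cluster and gene), ranks cluster markers by

    log2FC = log2(B + eps) - log2(A + eps)

where B is a gene's average normalized expression in the cluster of
interest and A the median of its averages over the other clusters,
assigns cell types from a marker reference, merges clusters whose top
markers coincide (duplicated-cluster artifacts), and flags clusters
whose top markers are dominated by stress (heat-shock) or ribosomal
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import NormalizedMatrix, RIBOSOMAL_PREFIXES

#: Drosophila heat-shock protein genes commonly topping stressed-cell clusters
DEFAULT_STRESS_GENES = (
    "Hsp22", "Hsp23", "Hsp26", "Hsp27", "Hsp67Ba", "Hsp67Bb", "Hsp67Bc",
    "Hsp68", "Hsp70Aa", "Hsp70Ab", "Hsp70Ba", "Hsp70Bb", "Hsp70Bc",
    "Hsp83", "Hsc70-1", "Hsc70-2", "Hsc70-3", "Hsc70-4", "Hsc70-5",
)


@dataclass
class MarkerReference:
    """Known positive (and optionally negative) markers per cell type."""

    positive: dict[str, list[str]]
    negative: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for t, genes in self.positive.items():
            if not genes:
                raise ValueError(f"type {t!r} has no positive markers")

    @classmethod
    def from_tsv(cls, path) -> "MarkerReference":
        """Read a TSV with columns: type, direction (pos/neg), gene."""
        df = pd.read_csv(path, sep="\t")
        pos: dict[str, list[str]] = {}
        neg: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            target = pos if str(row["direction"]).startswith("pos") else neg
            target.setdefault(str(row["type"]), []).append(str(row["gene"]))
        return cls(positive=pos, negative=neg)

    def to_tsv(self, path) -> None:
        rows = [
            {"type": t, "direction": "positive", "gene": g}
            for t, genes in self.positive.items()
            for g in genes
        ] + [
            {"type": t, "direction": "negative", "gene": g}
            for t, genes in self.negative.items()
            for g in genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _cluster_cells(labeling: dict, barcodes: list[str]) -> dict:
    """Map cluster id -> column indices, validating coverage."""
    col = {bc: j for j, bc in enumerate(barcodes)}
    unknown = [bc for bc in labeling if bc not in col]
    if unknown:
        raise KeyError(f"labeled barcodes not in matrix: {unknown[:3]}")
    clusters: dict = {}
    for bc, cl in labeling.items():
        clusters.setdefault(cl, []).append(col[bc])
    return {cl: np.array(sorted(idx)) for cl, idx in clusters.items()}


def dot_plot_stats(
    norm: NormalizedMatrix,
    labeling: dict,
    genes: list[str],
) -> pd.DataFrame:
    """Per (cluster, gene): pct expressing, mean expression, scaled mean.

    pct_expressing is the fraction of the cluster's cells with nonzero
    expression; scaled_mean is the z-score of the cluster means across
    clusters (population SD; zero when the gene is flat across
    clusters).
    """
    gene_idx = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in gene_idx]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    clusters = _cluster_cells(labeling, norm.barcodes)
    cluster_ids = sorted(clusters, key=str)
    rows = []
    gi = np.array([gene_idx[g] for g in genes])
    means = np.zeros((len(cluster_ids), len(genes)))
    pcts = np.zeros_like(means)
    for ci, cl in enumerate(cluster_ids):
        sub = norm.values[np.ix_(gi, clusters[cl])]
        means[ci] = sub.mean(axis=1)
        pcts[ci] = (sub > 0).mean(axis=1)
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (means - mu) / sd, 0.0)
    for ci, cl in enumerate(cluster_ids):
        for gj, g in enumerate(genes):
            rows.append(
                {
                    "cluster": cl,
                    "gene": g,
                    "pct_expressing": pcts[ci, gj],
                    "mean_expr": means[ci, gj],
                    "scaled_mean": scaled[ci, gj],
                }
            )
    return pd.DataFrame(rows)


def rank_genes(
    norm: NormalizedMatrix,
    labeling: dict,
    cluster,
    eps: float = 1e-2,
    pooled_reference: bool = False,
) -> pd.DataFrame:
    """Rank genes for one cluster by log2FC against the other clusters.

    B is the gene's mean normalized expression over the cluster's
    cells; A is the median of the per-cluster means over all other
    clusters (or, with ``pooled_reference=True``, the median is taken
    over all cells outside the cluster pooled together).  Genes are
    sorted by descending log2FC = log2(B+eps) - log2(A+eps), ties
    broken by gene id.
    """
    clusters = _cluster_cells(labeling, norm.barcodes)
    if cluster not in clusters:
        raise KeyError(f"cluster {cluster!r} not in labeling")
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to rank against")
    own = clusters[cluster]
    b = norm.values[:, own].mean(axis=1)
    others = [cl for cl in clusters if cl != cluster]
    if pooled_reference:
        pooled = np.concatenate([clusters[cl] for cl in others])
        a = np.median(norm.values[:, pooled], axis=1)
    else:
        other_means = np.stack(
            [norm.values[:, clusters[cl]].mean(axis=1) for cl in others]
        )
        a = np.median(other_means, axis=0)
    log2fc = np.log2(b + eps) - np.log2(a + eps)
    pct_in = (norm.values[:, own] > 0).mean(axis=1)
    out_cols = np.concatenate([clusters[cl] for cl in others])
    pct_out = (norm.values[:, out_cols] > 0).mean(axis=1)
    df = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "B": b,
            "A": a,
            "log2FC": log2fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
        }
    )
    return df.sort_values(
        ["log2FC", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def rank_all_clusters(
    norm: NormalizedMatrix, labeling: dict, eps: float = 1e-2
) -> dict:
    """rank_genes for every cluster; mapping cluster -> ranking table."""
    cluster_ids = sorted(set(labeling.values()), key=str)
    return {cl: rank_genes(norm, labeling, cl, eps=eps) for cl in cluster_ids}


def assign_cell_types(
    stats: pd.DataFrame,
    ref: MarkerReference,
    min_score: float = 0.1,
) -> dict:
    """Assign each cluster a type from marker reference scores.

    score(type, cluster) = mean over the type's positive markers of
    (scaled_mean * pct_expressing) minus the same mean over its
    negative markers.  A cluster is assigned the argmax type if its
    score reaches ``min_score``, else "unassigned".  Missing markers
    are skipped with a warning; a type with no scorable marker is
    unscorable.  Ties break by type name.
    """
    if not ref.positive:
        raise ValueError("marker reference is empty")
    known_genes = set(stats["gene"])
    pivot = stats.set_index(["cluster", "gene"])
    product = (
        pivot["scaled_mean"] * pivot["pct_expressing"]
    )
    clusters = sorted(set(stats["cluster"]), key=str)
    out = {}
    for cl in clusters:
        best_type, best_score = None, -np.inf
        for type_name in sorted(ref.positive):
            pos = [g for g in ref.positive[type_name] if g in known_genes]
            missing = set(ref.positive[type_name]) - known_genes
            if missing:
                warnings.warn(
                    f"markers missing from matrix for type {type_name!r}: "
                    f"{sorted(missing)[:5]}",
                    stacklevel=2,
                )
            if not pos:
                continue  # unscorable type
            score = float(np.mean([product[(cl, g)] for g in pos]))
            neg = [g for g in ref.negative.get(type_name, []) if g in known_genes]
            if neg:
                score -= float(np.mean([product[(cl, g)] for g in neg]))
            if score > best_score:
                best_type, best_score = type_name, score
        if best_type is None or best_score < min_score:
            out[cl] = ("unassigned", best_score if best_type else float("nan"))
        else:
            out[cl] = (best_type, best_score)
    return out


def top_markers(rankings: dict, k: int = 10) -> dict:
    """Top-k marker gene set per cluster from rank_genes tables."""
    return {cl: list(df["gene"].head(k)) for cl, df in rankings.items()}


def merge_equivalent_clusters(
    labeling: dict,
    top_marker_sets: dict,
    jaccard_min: float = 0.6,
) -> tuple[dict, list[dict]]:
    """Union clusters whose top-marker sets largely coincide.

    Clusters with Jaccard similarity of their top-k marker sets at or
    above ``jaccard_min`` are merged (transitive closure); a merged
    cluster takes the lexicographically smallest member id.  Returns
    the relabeled mapping and a provenance record of the merges.
    """
    ids = sorted(top_marker_sets, key=str)
    parent = {cl: cl for cl in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sa, sb = set(top_marker_sets[a]), set(top_marker_sets[b])
            union = sa | sb
            jac = len(sa & sb) / len(union) if union else 0.0
            if jac >= jaccard_min:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb, key=str)] = min(ra, rb, key=str)
                merges.append({"cluster_a": a, "cluster_b": b, "jaccard": jac})
    canonical = {}
    for cl in ids:
        root = find(cl)
        members = [c for c in ids if find(c) == root]
        canonical[cl] = min(members, key=str)
    new_labeling = {bc: canonical.get(cl, cl) for bc, cl in labeling.items()}
    return new_labeling, merges


def flag_artifact_clusters(
    rankings: dict,
    stress_genes=DEFAULT_STRESS_GENES,
    ribo_prefixes=RIBOSOMAL_PREFIXES,
    k: int = 10,
    min_fraction: float = 0.5,
) -> set:
    """Clusters whose top markers are dominated by stress/ribosomal genes.

    A cluster is flagged (to be labeled "other" and excluded from
    composition testing, but retained in reports) iff at least
    ``min_fraction`` of its top-k markers are heat-shock/stress genes
    or carry a ribosomal prefix.
    """
    stress = set(stress_genes)
    prefixes = tuple(ribo_prefixes)
    flagged = set()
    for cl, df in rankings.items():
        top = list(df["gene"].head(k))
        hits = sum(1 for g in top if g in stress or g.startswith(prefixes))
        if top and hits / len(top) >= min_fraction:
            flagged.add(cl)
    return flagged


def baseline_clustering(
    norm: NormalizedMatrix,
    n_clusters: int,
    n_components: int = 20,
    seed: int = 0,
) -> dict:
    """Convenience stand-in clustering for synthetic data.

    A top-component PCA reduction followed by k-means with a fixed
    seed.  This is a deterministic baseline for exercising the
    annotation and composition stages on simulated matrices — not a
    reimplementation of the graph-based clustering used on real
    atlases, whose labels should be supplied as input.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = norm.values.T  # cells x genes
    n_components = min(n_components, min(x.shape) - 1)
    reduced = PCA(n_components=n_components, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(reduced)
    return {bc: int(l) for bc, l in zip(norm.barcodes, labels)}
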