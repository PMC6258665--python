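"""Cluster composition by genotype and replicate.

In a combined two-genotype dataset, most cell populations are expected
to contain cells of both genotypes; a population contributed almost
exclusively by one genotype (the mutant-specific cluster pattern) is
detected here with a hypergeometric enrichment test per cluster,
Benjamini-Hochberg correction across clusters, and a minimum-fraction
rule.  Replicate evenness per cluster is summarized by the number of
contributing replicates, the normalized Shannon entropy of the
within-cluster replicate proportions, and a chi-square test against
the global replicate proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CompositionTable:
    """Cluster x genotype and cluster x replicate cell counts."""

    genotype: pd.DataFrame   # index: cluster, columns: genotype
    replicate: pd.DataFrame  # index: cluster, columns: replicate
    genotype_totals: pd.Series = field(default=None)

    def __post_init__(self):
        if self.genotype_totals is None:
            self.genotype_totals = self.genotype.sum(axis=0)


def composition_table(labeling: dict, metadata: pd.DataFrame) -> CompositionTable:
    """Cross-tabulate cluster membership against genotype and replicate.

    ``metadata`` is indexed by barcode with columns genotype and
    replicate; every labeled barcode must be present.
    """
    missing = [bc for bc in labeling if bc not in metadata.index]
    if missing:
        raise KeyError(f"barcodes missing metadata: {missing[:5]}")
    barcodes = list(labeling)
    df = pd.DataFrame(
        {
            "cluster": [labeling[bc] for bc in barcodes],
            "genotype": metadata.loc[barcodes, "genotype"].to_numpy(),
            "replicate": metadata.loc[barcodes, "replicate"].to_numpy(),
        }
    )
    geno = pd.crosstab(df["cluster"], df["genotype"])
    rep = pd.crosstab(df["cluster"], df["replicate"])
    return CompositionTable(genotype=geno, replicate=rep)


def genotype_specific_clusters(
    table: CompositionTable,
    focal_genotype: str,
    min_frac: float = 0.9,
    alpha: float = 0.05,
    min_cluster_size: int = 20,
    exclude_clusters=(),
) -> pd.DataFrame:
    """Flag clusters contributed almost exclusively by one genotype.

    For every cluster of at least ``min_cluster_size`` cells, the
    focal-genotype count is tested against the global genotype totals
    with a hypergeometric upper-tail p (sampling the cluster without
    replacement from the pooled dataset); p-values are BH-adjusted
    across the tested clusters.  A cluster is flagged iff its focal
    fraction reaches ``min_frac`` and its adjusted q is at most
    ``alpha``.  Smaller clusters are reported untested.
    """
    if focal_genotype not in table.genotype.columns:
        raise KeyError(f"genotype {focal_genotype!r} absent from table")
    if table.genotype.shape[1] < 2:
        raise ValueError("need at least 2 genotypes")
    total = int(table.genotype.to_numpy().sum())
    total_focal = int(table.genotype_totals[focal_genotype])
    rows = []
    for cluster, counts in table.genotype.iterrows():
        n = int(counts.sum())
        k = int(counts[focal_genotype])
        tested = n >= min_cluster_size and cluster not in set(exclude_clusters)
        p = (
            float(scipy.stats.hypergeom.sf(k - 1, total, total_focal, n))
            if tested
            else np.nan
        )
        rows.append(
            {
                "cluster": cluster,
                "n": n,
                "n_focal": k,
                "frac_focal_genotype": k / n if n else np.nan,
                "tested": tested,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    out["q"] = np.nan
    tested_mask = out["tested"].to_numpy()
    if tested_mask.any():
        _, q, _, _ = multipletests(
            out.loc[tested_mask, "p_raw"], method="fdr_bh"
        )
        out.loc[tested_mask, "q"] = q
    out["flagged"] = (
        out["tested"]
        & (out["frac_focal_genotype"] >= min_frac)
        & (out["q"] <= alpha)
    )
    return out


def replicate_evenness(table: CompositionTable) -> pd.DataFrame:
    """Per-cluster replicate occupancy, entropy and chi-square evenness.

    entropy_norm is the Shannon entropy of the within-cluster replicate
    proportions divided by log(#replicates): 1 iff all replicates
    contribute equally, 0 for a single-replicate cluster.  The
    chi-square p compares the cluster's replicate counts with the
    global replicate proportions.
    """
    if table.replicate.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    n_reps = table.replicate.shape[1]
    global_counts = table.replicate.sum(axis=0).to_numpy(dtype=float)
    global_props = global_counts / global_counts.sum()
    rows = []
    for cluster, counts in table.replicate.iterrows():
        c = counts.to_numpy(dtype=float)
        n = c.sum()
        props = c / n
        nz = props[props > 0]
        entropy = float(-(nz * np.log(nz)).sum()) / np.log(n_reps)
        expected = global_props * n
        # chi-square against the global replicate mix
        chi2 = float(((c - expected) ** 2 / expected).sum())
        p = float(scipy.stats.chi2.sf(chi2, df=n_reps - 1))
        rows.append(
            {
                "cluster": cluster,
                "n": int(n),
                "n_replicates_present": int((c > 0).sum()),
                "entropy_norm": entropy,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
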