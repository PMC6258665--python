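"""End-to-end orchestration: simulate/load -> cell call -> QC -> annotate
-> doublet assessment -> composition tests -> marker ranking -> GSEA.

All stage parameters live in one :class:`PipelineConfig`; all
randomness flows from its single seed, so identical (config, seed)
runs produce identical outputs.  Every stage appends an entry to the
run manifest (input/output sizes plus any warnings), and every input
barcode is accounted for in exactly one of kept / ambient-rejected /
QC-removed / signature-excluded.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, doublets, gsea, markers, qc, simulate
from .io import CountMatrix, read_dge, write_dge


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


_QC_DEFAULTS = {
    "min_genes": 200,
    "max_genes": 3000,
    "min_cells": 3,
    "scale_factor": 1e4,
    "signature_threshold": 0.4,
}
_GENOTYPE_DEFAULTS = {
    "focal_genotype": None,
    "min_frac": 0.9,
    "alpha": 0.05,
    "min_cluster_size": 20,
}
_GSEA_DEFAULTS = {
    "n_perm": 10000,
    "fdr_cutoff": 0.05,
    "weight_p": 1.0,
    "min_size": 5,
    "max_size": 500,
    "clusters": None,  # clusters to rank and run GSEA on; None = all
}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``sim`` (a synthetic-data configuration) or ``dge_path`` +
    ``metadata_path`` must be provided.  Cluster labels come from
    ``clusters_path``, from the synthetic ground truth
    (``use_truth_clusters``), or from the baseline stand-in clustering
    (synthetic convenience only).
    """

    out_dir: str = "dropatlas_run"
    seed: int = 0
    sim: dict | None = None
    dge_path: str | None = None
    metadata_path: str | None = None
    clusters_path: str | None = None
    use_truth_clusters: bool = True
    baseline_n_clusters: int | None = None
    skip_knee: bool = False
    qc: dict = field(default_factory=lambda: dict(_QC_DEFAULTS))
    marker_pairs: list = field(default_factory=list)  # [gene_a, gene_b, label]
    pair_clusters: list | None = None  # cluster subset for the doublet test
    marker_reference_path: str | None = None
    min_assign_score: float = 0.1
    gmt_path: str | None = None
    genotype: dict = field(default_factory=lambda: dict(_GENOTYPE_DEFAULTS))
    gsea: dict = field(default_factory=lambda: dict(_GSEA_DEFAULTS))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN_KEYS = set(PipelineConfig.__dataclass_fields__)


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a YAML/JSON config, collecting all errors.

    Unknown keys are rejected (typo protection); every violation is
    reported at once in a single :class:`ConfigError`.
    """
    if isinstance(path_or_dict, (str, Path)):
        path = Path(path_or_dict)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    else:
        data = dict(path_or_dict)
    errors: list[str] = []
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in data.items() if k in _KNOWN_KEYS})
    for section, defaults in (
        ("qc", _QC_DEFAULTS),
        ("genotype", _GENOTYPE_DEFAULTS),
        ("gsea", _GSEA_DEFAULTS),
    ):
        merged = dict(defaults)
        given = getattr(cfg, section) or {}
        bad = set(given) - set(defaults)
        if bad:
            errors.append(f"unknown keys in {section!r}: {sorted(bad)}")
        merged.update({k: v for k, v in given.items() if k in defaults})
        setattr(cfg, section, merged)
    if cfg.sim is None and cfg.dge_path is None:
        errors.append("either 'sim' or 'dge_path' must be given")
    if cfg.sim is not None and cfg.dge_path is not None:
        errors.append("'sim' and 'dge_path' are mutually exclusive")
    if cfg.dge_path is not None and cfg.metadata_path is None:
        errors.append("'metadata_path' required when loading a DGE matrix")
    if cfg.qc["min_genes"] > cfg.qc["max_genes"]:
        errors.append(
            f"min_genes {cfg.qc['min_genes']} exceeds max_genes {cfg.qc['max_genes']}"
        )
    if cfg.gmt_path is None and cfg.gsea.get("clusters"):
        errors.append("GSEA clusters requested but no 'gmt_path' given")
    for p in (cfg.dge_path, cfg.metadata_path, cfg.clusters_path,
              cfg.marker_reference_path, cfg.gmt_path):
        if p is not None and not Path(p).exists():
            errors.append(f"path does not exist: {p}")
    for pair in cfg.marker_pairs:
        if len(pair) < 2:
            errors.append(f"marker pair needs gene_a and gene_b: {pair}")
    if errors:
        raise ConfigError(errors)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest.

    Stage outputs are written under ``config.out_dir`` as TSV/JSON plus
    a markdown summary; the manifest records per-stage input/output
    sizes and warnings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    captured: list[str] = []

    def stage(name: str, n_in: int, n_out: int, **extra):
        manifest["stages"][name] = {"n_in": n_in, "n_out": n_out, **extra}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # -- input -----------------------------------------------------
        if config.sim is not None:
            sim_cfg = simulate.SimConfig.from_dict(config.sim)
            sim_cfg.seed = config.seed
            matrix, truth = simulate.simulate_counts(sim_cfg)
            metadata = truth
            simulate.write_truth(truth, out / "truth.tsv")
        else:
            matrix = read_dge(config.dge_path)
            metadata = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
            truth = None
        stage("input", matrix.n_cells, matrix.n_cells, n_genes=matrix.n_genes)

        # -- knee-plot cell calling -------------------------------------
        if config.skip_knee:
            called = matrix
            ambient_rejected: list[str] = []
        else:
            knee = qc.knee_call(matrix.library_sizes())
            order = np.argsort(-matrix.library_sizes(), kind="stable")
            keep = np.zeros(matrix.n_cells, dtype=bool)
            keep[order[: knee.n_cells_selected]] = True
            ambient_rejected = [b for b, k in zip(matrix.barcodes, keep) if not k]
            called = matrix.subset_cells(keep)
            stage(
                "knee_call",
                matrix.n_cells,
                called.n_cells,
                read_threshold=knee.read_threshold,
            )

        # -- QC filters -------------------------------------------------
        filtered = qc.filter_cells_genes(
            called,
            min_genes=config.qc["min_genes"],
            max_genes=config.qc["max_genes"],
            min_cells=config.qc["min_cells"],
        )
        excluded_sig = qc.exclude_signature_cells(
            filtered, fraction_threshold=config.qc["signature_threshold"]
        )
        if excluded_sig:
            keep = [b not in set(excluded_sig) for b in filtered.barcodes]
            filtered = filtered.subset_cells(np.array(keep))
        qc_removed = [
            b for b in called.barcodes
            if b not in set(filtered.barcodes) and b not in set(excluded_sig)
        ]
        qc.qc_report(
            called,
            min_genes=config.qc["min_genes"],
            max_genes=config.qc["max_genes"],
            signature_threshold=config.qc["signature_threshold"],
        ).to_csv(out / "qc_report.tsv", sep="\t")
        stage("qc_filter", called.n_cells, filtered.n_cells,
              n_genes=filtered.n_genes, signature_excluded=len(excluded_sig))

        # barcode accounting: kept / ambient / qc-removed / signature
        accounting = {
            "kept": filtered.n_cells,
            "ambient_rejected": len(ambient_rejected),
            "qc_removed": len(qc_removed),
            "signature_excluded": len(excluded_sig),
        }
        manifest["barcode_accounting"] = accounting

        norm = qc.normalize(filtered, scale_factor=config.qc["scale_factor"])

        # -- cluster labels ---------------------------------------------
        if config.clusters_path is not None:
            lab_df = pd.read_csv(config.clusters_path, sep="\t", index_col=0)
            labeling = {
                bc: lab_df.loc[bc, "cluster"]
                for bc in filtered.barcodes
                if bc in lab_df.index
            }
        elif config.sim is not None and config.use_truth_clusters:
            labeling = {
                bc: truth.loc[bc, "cell_type"]
                for bc in filtered.barcodes
                if not truth.loc[bc, "is_ambient"]
            }
        elif config.baseline_n_clusters:
            labeling = markers.baseline_clustering(
                norm, config.baseline_n_clusters, seed=config.seed
            )
        else:
            raise ConfigError(["no cluster labels available"])
        stage("cluster_labels", filtered.n_cells, len(labeling),
              n_clusters=len(set(labeling.values())))

        # -- marker ranking, merging, artifact flagging ------------------
        rankings = markers.rank_all_clusters(norm, labeling)
        tops = markers.top_markers(rankings, k=10)
        labeling, merges = markers.merge_equivalent_clusters(labeling, tops)
        if merges:
            rankings = markers.rank_all_clusters(norm, labeling)
            tops = markers.top_markers(rankings, k=10)
        artifact = markers.flag_artifact_clusters(rankings)
        (out / "merges.json").write_text(
            json.dumps({"merges": merges, "artifact_clusters": sorted(map(str, artifact))},
                       indent=2, sort_keys=True)
        )
        for cl, df in rankings.items():
            df.head(50).to_csv(out / f"markers_cluster_{cl}.tsv", sep="\t", index=False)
        stage("annotation", len(set(labeling.values())),
              len(set(labeling.values())) - len(artifact),
              merged_pairs=len(merges), artifact_clusters=len(artifact))

        # -- reference-based type assignment -----------------------------
        assignments = None
        if config.marker_reference_path is not None:
            ref = markers.MarkerReference.from_tsv(config.marker_reference_path)
            ref_genes = sorted(
                {g for genes in ref.positive.values() for g in genes if g in set(norm.gene_ids)}
            )
            stats = markers.dot_plot_stats(norm, labeling, ref_genes)
            stats.to_csv(out / "dot_plot_stats.tsv", sep="\t", index=False)
            assignments = markers.assign_cell_types(
                stats, ref, min_score=config.min_assign_score
            )
            pd.DataFrame(
                [(cl, t, s) for cl, (t, s) in assignments.items()],
                columns=["cluster", "assigned_type", "score"],
            ).to_csv(out / "assignments.tsv", sep="\t", index=False)

        # -- doublet co-expression ---------------------------------------
        pair_results = []
        if config.marker_pairs:
            if config.pair_clusters is not None:
                subset = [
                    bc for bc, cl in labeling.items()
                    if cl in set(config.pair_clusters)
                ]
            else:
                subset = list(labeling)
            for pair_spec in config.marker_pairs:
                pair = doublets.MarkerPair(
                    gene_a=pair_spec[0],
                    gene_b=pair_spec[1],
                    label=pair_spec[2] if len(pair_spec) > 2 else "",
                )
                table = doublets.coexpression_table(filtered, subset, pair)
                try:
                    pair_results.append(doublets.independence_test(table, pair))
                except doublets.UndefinedStatisticError as err:
                    manifest["warnings"].append(
                        f"pair {pair.label or pair.gene_a + '/' + pair.gene_b}: "
                        f"chi-square undefined (exp_frac={err.exp_frac:.3g})"
                    )
            if pair_results:
                doublets.results_table(pair_results).to_csv(
                    out / "coexpression.tsv", sep="\t", index=False
                )
                chi2_tot, df_tot, p_comb = doublets.combined_test(pair_results)
                purity = doublets.singlet_purity(pair_results)
                stage("doublet_qc", len(subset), len(pair_results),
                      combined_chi2=chi2_tot, combined_df=df_tot,
                      combined_p=p_comb, singlet_purity=purity)

        # -- composition tests -------------------------------------------
        geno_result = None
        if metadata is not None and "genotype" in metadata.columns:
            comp = composition.composition_table(labeling, metadata)
            comp.genotype.to_csv(out / "composition_genotype.tsv", sep="\t")
            comp.replicate.to_csv(out / "composition_replicate.tsv", sep="\t")
            focal = config.genotype["focal_genotype"]
            if focal is None and comp.genotype.shape[1] >= 2:
                # default: the rarer genotype (the perturbation arm)
                focal = comp.genotype_totals.idxmin()
            if focal is not None and comp.genotype.shape[1] >= 2:
                geno_result = composition.genotype_specific_clusters(
                    comp,
                    focal_genotype=focal,
                    min_frac=config.genotype["min_frac"],
                    alpha=config.genotype["alpha"],
                    min_cluster_size=config.genotype["min_cluster_size"],
                    exclude_clusters=artifact,
                )
                geno_result.to_csv(out / "genotype_enrichment.tsv", sep="\t")
                stage("genotype_test", comp.genotype.shape[0],
                      int(geno_result["flagged"].sum()), focal_genotype=str(focal))
            if comp.replicate.shape[1] >= 2:
                evenness = composition.replicate_evenness(comp)
                evenness.to_csv(out / "replicate_evenness.tsv", sep="\t")

        # -- GSEA ---------------------------------------------------------
        if config.gmt_path is not None:
            collection = gsea.read_gmt(config.gmt_path)
            gsea_clusters = config.gsea.get("clusters") or sorted(
                set(labeling.values()) - artifact, key=str
            )
            reports = {}
            for cl in gsea_clusters:
                ranking = rankings[cl]
                ranked = gsea.RankedList.from_scores(
                    ranking["gene"], ranking["log2FC"]
                )
                results, skipped = gsea.prerank(
                    ranked,
                    collection,
                    weight_p=config.gsea["weight_p"],
                    n_perm=config.gsea["n_perm"],
                    min_size=config.gsea["min_size"],
                    max_size=config.gsea["max_size"],
                    seed=config.seed,
                )
                rep = gsea.report(results, fdr_cutoff=config.gsea["fdr_cutoff"])
                rep.to_csv(out / f"gsea_cluster_{cl}.tsv", sep="\t", index=False)
                reports[str(cl)] = rep
            if reports:
                gsea.fdr_matrix(reports).to_csv(out / "gsea_fdr_matrix.tsv", sep="\t")
                stage("gsea", len(gsea_clusters), len(collection))

        captured = [str(w.message) for w in wlist]

    manifest["warnings"].extend(captured)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _write_summary(out, manifest, geno_result)
    return manifest


def _write_summary(out: Path, manifest: dict, geno_result) -> None:
    lines = ["# Pipeline run summary", ""]
    lines.append(f"- config hash: `{manifest['config_hash']}`")
    lines.append(f"- seed: {manifest['seed']}")
    lines.append("")
    lines.append("| stage | in | out |")
    lines.append("|---|---|---|")
    for name, entry in manifest["stages"].items():
        lines.append(f"| {name} | {entry['n_in']} | {entry['n_out']} |")
    if geno_result is not None:
        flagged = geno_result.index[geno_result["flagged"]].tolist()
        lines.append("")
        lines.append(
            f"Genotype-restricted clusters flagged: {flagged if flagged else 'none'}"
        )
    if manifest["warnings"]:
        lines.append("")
        lines.append("Warnings:")
        for w in manifest["warnings"]:
            lines.append(f"- {w}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
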