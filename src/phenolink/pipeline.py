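"""One-click pipeline: configuration, stage orchestration, and the run
manifest.

Stages execute in a fixed order — phenotype profiling, preprocessing/QC,
annotation, feature discovery (DE, PCA, clustering), per-feature
association, enrichment — and each stage writes its CSV before the next
starts, so a partial run still leaves usable intermediates.  Optional
stages missing their inputs (no QC samples named, no GMT supplied) are
skipped with a logged warning; hard errors abort with the manifest of
completed stages attached to the exception.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_features
from .core_data import (
    ExpressionMatrix,
    PhenotypeTable,
    read_annotation_table,
    annotate_features,
    read_expression_matrix,
    read_phenotype_table,
    write_expression_matrix,
)
from .enrichment import features_to_genes, ora, read_gmt
from .feature_discovery import (
    DEConfig,
    cluster_features,
    differential_expression,
    pca_contribution,
)
from .preprocess_qc import (
    PreprocessConfig,
    filter_noise_features,
    impute,
    log2_transform,
    median_normalize,
    qc_replicate_report,
)
from .profiling import correlate_phenotypes, profile_phenotypes

logger = logging.getLogger("phenolink")

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]

STAGES = ("profile", "preprocess", "qc", "annotate", "de", "pca",
          "cluster", "associate", "enrich")


class PipelineError(RuntimeError):
    """Hard pipeline failure; carries the manifest of completed stages."""

    def __init__(self, message: str, manifest: "RunManifest | None" = None):
        super().__init__(message)
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults match the tool's standard settings
    (median target 0, 50% noise filter, FC 1.5 / adj-p 0.01 gate, top 100
    contribution features, association alpha 0.05)."""

    matrix_path: str = ""
    phenotype_path: str = ""
    annotation_path: str | None = None
    annotation_key_columns: list[str] = field(default_factory=lambda: ["gene"])
    annotation_url_template: str | None = None
    annotation_mode: str = "gene"
    gmt_paths: list[str] = field(default_factory=list)
    out_dir: str = "phenolink_out"
    seed: int = 0
    allow_subset: bool = False
    qc_sample_ids: list[str] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    de: DEConfig = field(default_factory=DEConfig)
    pca_n_components: int = 10
    pca_top_k: int = 100
    cluster_k: int = 4
    association_alpha: float = 0.05
    associate_all_features: bool = False
    ora_min_size: int = 5
    ora_max_size: int = 2000
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    plots: bool = False

    def __post_init__(self) -> None:
        enabled = dict.fromkeys(STAGES, True)
        enabled.update(self.stages)
        unknown = set(enabled) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage flags: {sorted(unknown)}")
        self.stages = enabled

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "de" in raw:
            raw["de"] = DEConfig(**raw["de"])
        return cls(**raw)

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, software version,
    per-stage outputs with row counts, warnings, and timing."""

    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[tuple[str, int]], seconds: float) -> None:
        self.stages.append({
            "stage": name,
            "outputs": [{"file": f, "rows": r} for f, r in outputs],
            "seconds": round(seconds, 3),
        })

    def warn(self, message: str) -> None:
        logger.warning(message)
        self.warnings.append(message)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "config": self.config,
                 "stages": self.stages, "warnings": self.warnings},
                fh, indent=2, default=str,
            )
            fh.write("\n")


def _write_csv(df: pd.DataFrame, path: Path) -> tuple[str, int]:
    df.to_csv(path, index=False)
    return path.name, len(df)


def _check_alignment(m: ExpressionMatrix, p: PhenotypeTable, cfg: PipelineConfig,
                     manifest: RunManifest) -> tuple[ExpressionMatrix, PhenotypeTable]:
    m_ids, p_ids = set(m.sample_ids), set(p.sample_ids)
    if m_ids == p_ids:
        return m, PhenotypeTable(p.data.loc[m.sample_ids], p.kinds)
    only_m = sorted(m_ids - p_ids)
    only_p = sorted(p_ids - m_ids)
    if not cfg.allow_subset:
        raise PipelineError(
            "sample names differ between matrix and phenotype table "
            f"(matrix only: {only_m[:10]}; phenotypes only: {only_p[:10]}); "
            "pass allow_subset to run on the intersection",
            manifest,
        )
    shared = [s for s in m.sample_ids if s in p_ids]
    if not shared:
        raise PipelineError("matrix and phenotype table share no samples", manifest)
    manifest.warn(
        f"running on {len(shared)} shared samples "
        f"(dropped {len(only_m)} matrix-only, {len(only_p)} phenotype-only)"
    )
    return (
        ExpressionMatrix(m.data.loc[shared], m.log2_transformed),
        PhenotypeTable(p.data.loc[shared], p.kinds),
    )


def _maybe_plots(out: Path, de_table: pd.DataFrame | None, pca_result) -> list[tuple[str, int]]:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping static plots")
        return []
    written = []
    if de_table is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        t = de_table.dropna(subset=["log2_fc", "adj_p"])
        colors = t["direction"].map({"up": "crimson", "down": "steelblue", "ns": "0.7"})
        ax.scatter(t["log2_fc"], -np.log10(t["adj_p"].clip(lower=1e-300)),
                   s=6, c=colors, linewidths=0)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 adjusted p")
        fig.tight_layout()
        fig.savefig(out / "volcano.png", dpi=120)
        plt.close(fig)
        written.append(("volcano.png", len(t)))
    if pca_result is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        s = pca_result.scores
        ax.scatter(s.iloc[:, 0], s.iloc[:, 1], s=12)
        vr = pca_result.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({vr[0]:.1%})")
        ax.set_ylabel(f"PC2 ({vr[1]:.1%})" if len(vr) > 1 else "PC2")
        fig.tight_layout()
        fig.savefig(out / "pca_scores.png", dpi=120)
        plt.close(fig)
        written.append(("pca_scores.png", len(s)))
    return written


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order, writing CSVs under cfg.out_dir.

    Identical config + inputs + seed produce byte-identical CSVs; the only
    run-to-run differences live in the manifest's timing fields.
    """
    manifest = RunManifest(config=cfg.snapshot())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_expression_matrix(
        cfg.matrix_path, log2_transformed=not cfg.preprocess.apply_log2
    )
    phenotypes = read_phenotype_table(cfg.phenotype_path)
    matrix, phenotypes = _check_alignment(matrix, phenotypes, cfg, manifest)

    def stage(name: str) -> bool:
        return bool(cfg.stages.get(name, True))

    de_result = None
    pca_result = None
    cluster_result = None
    assoc_table = None

    if stage("profile"):
        t0 = time.perf_counter()
        profile = profile_phenotypes(phenotypes)
        outputs = [_write_csv(profile.table, out / "phenotype_profile.csv")]
        if len(phenotypes.phenotype_names) >= 2:
            corr = correlate_phenotypes(phenotypes)
            outputs.append(_write_csv(corr.to_long_frame(), out / "phenotype_correlation.csv"))
        else:
            manifest.warn("fewer than 2 phenotypes; skipping phenotype correlation")
        manifest.add_stage("profile", outputs, time.perf_counter() - t0)

    if stage("preprocess"):
        t0 = time.perf_counter()
        pp = cfg.preprocess
        if pp.apply_log2:
            matrix = log2_transform(matrix)
        matrix = median_normalize(matrix, pp.normalization_target)
        matrix, removed = filter_noise_features(matrix, pp.min_observed_fraction)
        n_missing = int(matrix.missing_mask().to_numpy().sum())
        matrix = impute(matrix, pp.imputation_method, pp.imputation_scale)
        logger.info(
            "preprocess: removed %d noise features, imputed %d values",
            len(removed), n_missing,
        )
        write_expression_matrix(matrix, str(out / "preprocessed_matrix.csv"))
        removed_df = pd.DataFrame({"removed_feature": removed})
        outputs = [
            ("preprocessed_matrix.csv", matrix.n_samples),
            _write_csv(removed_df, out / "removed_features.csv"),
        ]
        manifest.add_stage("preprocess", outputs, time.perf_counter() - t0)
    elif matrix.missing_mask().to_numpy().any():
        matrix = impute(matrix, cfg.preprocess.imputation_method,
                        cfg.preprocess.imputation_scale)
        manifest.warn("preprocess disabled but matrix has missing values; imputed for PCA/clustering")

    if stage("qc"):
        if len(cfg.qc_sample_ids) >= 2:
            t0 = time.perf_counter()
            report = qc_replicate_report(matrix, cfg.qc_sample_ids)
            outputs = [_write_csv(report.to_long_frame(), out / "qc_report.csv")]
            manifest.add_stage("qc", outputs, time.perf_counter() - t0)
        else:
            manifest.warn("no QC samples configured; skipping QC stage")

    if stage("annotate"):
        if cfg.annotation_path:
            t0 = time.perf_counter()
            db = read_annotation_table(
                cfg.annotation_path, cfg.annotation_key_columns,
                cfg.annotation_url_template,
            )
            annotated = annotate_features(matrix.feature_ids, db, cfg.annotation_mode)
            outputs = [_write_csv(annotated, out / "annotations.csv")]
            manifest.add_stage("annotate", outputs, time.perf_counter() - t0)
        else:
            manifest.warn("no annotation database configured; skipping annotation")

    if stage("de"):
        t0 = time.perf_counter()
        de_result = differential_expression(matrix, phenotypes, cfg.de)
        outputs = [_write_csv(de_result.table, out / "de_results.csv")]
        manifest.add_stage("de", outputs, time.perf_counter() - t0)

    if stage("pca"):
        t0 = time.perf_counter()
        pca_result = pca_contribution(matrix, cfg.pca_n_components, cfg.pca_top_k)
        vr_df = pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(pca_result.explained_variance_ratio))],
            "explained_variance_ratio": pca_result.explained_variance_ratio,
        })
        top_rows = [
            {"component": pc, "rank": rank + 1, "feature": feat,
             "loading": pca_result.loadings.loc[pc, feat]}
            for pc, feats in pca_result.top_per_component.items()
            for rank, feat in enumerate(feats)
        ]
        outputs = [
            _write_csv(pca_result.contribution_table(), out / "pca_contributions.csv"),
            _write_csv(vr_df, out / "pca_variance.csv"),
            _write_csv(pd.DataFrame(top_rows), out / "pca_top_features.csv"),
        ]
        manifest.add_stage("pca", outputs, time.perf_counter() - t0)

    if stage("cluster"):
        t0 = time.perf_counter()
        k = min(cfg.cluster_k, matrix.n_features)
        cluster_result = cluster_features(matrix, k)
        outputs = [_write_csv(cluster_result.to_frame(), out / "clusters.csv")]
        manifest.add_stage("cluster", outputs, time.perf_counter() - t0)

    if stage("associate"):
        t0 = time.perf_counter()
        if cfg.associate_all_features:
            selected = list(matrix.feature_ids)
        else:
            selected = []
            seen = set()
            pools: list[list[str]] = []
            if de_result is not None:
                pools.append(list(de_result.significant["feature"]))
            if pca_result is not None:
                pools.append(pca_result.top_features)
            for pool in pools:
                for f in pool:
                    if f not in seen:
                        seen.add(f)
                        selected.append(f)
            if not selected:
                selected = list(matrix.feature_ids)
                manifest.warn("no upstream feature selection available; associating all features")
        assoc_table = associate_features(
            matrix, phenotypes, cfg.de.group_phenotype,
            features=selected, alpha=cfg.association_alpha,
        )
        outputs = [_write_csv(assoc_table, out / "associations.csv")]
        manifest.add_stage("associate", outputs, time.perf_counter() - t0)

    if stage("enrich"):
        if cfg.gmt_paths and de_result is not None:
            t0 = time.perf_counter()
            background = features_to_genes(matrix.feature_ids)
            frames = []
            for gmt_path in cfg.gmt_paths:
                collection = read_gmt(gmt_path)
                for direction in ("up", "down"):
                    feats = de_result.features_by_direction(direction)
                    if not feats:
                        continue
                    query = features_to_genes(feats)
                    res = ora(query, background, collection,
                              cfg.ora_min_size, cfg.ora_max_size)
                    res.insert(0, "collection", collection.name)
                    res.insert(1, "query", direction)
                    frames.append(res)
            enr = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["collection", "query", "set", "p", "adj_p"]))
            outputs = [_write_csv(enr, out / "enrichment.csv")]
            manifest.add_stage("enrich", outputs, time.perf_counter() - t0)
        else:
            manifest.warn("no GMT collection or no DE results; skipping enrichment")

    if cfg.plots:
        t0 = time.perf_counter()
        de_table = de_result.table if de_result is not None else None
        written = _maybe_plots(out, de_table, pca_result)
        if written:
            manifest.add_stage("plots", written, time.perf_counter() - t0)

    manifest.write(str(out / "manifest.json"))
    return manifest
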