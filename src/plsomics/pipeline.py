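"""End-to-end pipeline: simulate/load -> preprocess -> select -> integrate
-> evaluate -> interpret, with a reproducibility manifest.

Seeding: a single master seed lives in the config; each stochastic stage
derives its own stream at a documented offset (simulation: seed, splits:
seed + 10_000) so stages can be re-run in isolation.  All other stages are
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .blocks import OmicsBlock
from .blockplsda import BlockPLSDA
from .evaluate import (
    DEFAULT_KEEPX,
    evaluate_over_splits,
    majority_baseline,
    make_splits,
    run_persistence_selection,
)
from .interpret import (
    build_network,
    cluster_heatmap_order,
    cross_omics_association,
    feature_component_correlations,
)
from .io import read_labels, read_matrix
from .preprocess import (
    assemble_phenotype_block,
    autoscale,
    beta_to_m,
    preprocess_expression,
    qc_genotypes,
)
from .simulate import SyntheticConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "preprocess_cohort"]

logger = logging.getLogger(__name__)

SPLIT_SEED_OFFSET = 10_000


@dataclass
class PipelineConfig:
    """All workflow constants in one place.

    ``paths`` maps block name -> matrix path (plus ``labels``); when empty,
    a synthetic cohort is generated from ``synthetic``.
    """

    paths: dict = field(default_factory=dict)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eps: float = 1e-6
    miss_thresh: float = 0.05
    hwe_alpha: float = 1e-6
    min_median_count: float = 1.0
    n_components: int = 2
    keep_x: dict = field(default_factory=lambda: dict(DEFAULT_KEEPX))
    design_inter_block: float = 1.0
    n_splits: int = 100
    train_frac: float = 0.8
    persistence_threshold: float = 0.70
    network_threshold: float = 0.7
    seed: int = 0
    out_dir: str = "plsomics_results"

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.persistence_threshold <= 1:
            raise ValueError("persistence_threshold must lie in (0, 1]")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "synthetic" in payload and isinstance(payload["synthetic"], dict):
            syn = dict(payload["synthetic"])
            for key in ("library_size_range", "maf_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            payload["synthetic"] = SyntheticConfig(**syn)
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                payload = yaml.safe_load(fh)
            else:
                payload = json.load(fh)
        return cls.from_dict(payload or {})

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    qc_reports: list = field(default_factory=list)

    def log_stage(self, name: str, wall_time: float, **info) -> None:
        entry = {"stage": name, "wall_time_s": round(wall_time, 3), **info}
        self.stages.append(entry)
        logger.info("stage %s finished in %.2fs %s", name, wall_time, info)

    def checksum(self, path: str) -> None:
        with open(path, "rb") as fh:
            self.checksums[os.path.basename(path)] = hashlib.sha256(
                fh.read()
            ).hexdigest()

    def write(self, path: str) -> None:
        payload = {
            "config": self.config, "version": self.version, "seed": self.seed,
            "stages": self.stages, "checksums": self.checksums,
            "qc_reports": self.qc_reports,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def preprocess_cohort(cohort, config: PipelineConfig):
    """Preprocess a SyntheticCohort's raw blocks into model-ready blocks.

    Returns ``(blocks, qc_reports)`` where blocks are expression (log2 of
    median-of-ratios-normalized counts), methylation (M-values), genotype
    (post-QC, imputed) and phenotype.
    """
    expr_block, expr_report = preprocess_expression(
        cohort.expression_counts.values.T,
        cohort.expression_counts.feature_ids,
        cohort.sample_ids,
    )
    m_values = beta_to_m(cohort.methylation_beta.values, eps=config.eps)
    meth_block = OmicsBlock(
        m_values, cohort.sample_ids, cohort.methylation_beta.feature_ids,
        "methylation",
    )
    geno_block, geno_report = qc_genotypes(
        cohort.genotype_dosage, miss_thresh=config.miss_thresh,
        hwe_alpha=config.hwe_alpha,
    )
    pheno_block = assemble_phenotype_block(cohort.phenotypes)
    blocks = [expr_block, meth_block, geno_block, pheno_block]
    return blocks, [expr_report.to_dict(), geno_report.to_dict()]


def _load_blocks(config: PipelineConfig):
    paths = config.paths
    required = ["expression", "methylation", "genotype", "phenotype", "labels"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"config.paths lacks {missing}")
    for key in required:
        if not os.path.exists(paths[key]):
            raise FileNotFoundError(f"input for {key!r} not found: {paths[key]}")
    import pandas as pd

    expression = read_matrix(paths["expression"], "expression")
    methylation = read_matrix(paths["methylation"], "methylation")
    genotype = read_matrix(paths["genotype"], "genotype")
    phenotype = pd.read_csv(paths["phenotype"], sep="\t", index_col=0)
    sample_ids, y = read_labels(paths["labels"])

    from .simulate import PlantedTruth, SyntheticCohort

    labels = np.asarray(y)
    cohort = SyntheticCohort(
        labels=labels, expression_counts=expression, methylation_beta=methylation,
        genotype_dosage=genotype, phenotypes=phenotype,
        truth=PlantedTruth(informative={}), config=config.synthetic,
    )
    if expression.sample_ids != sample_ids:
        raise ValueError("label file sample order does not match the matrices")
    return cohort


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow and write result files + manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           seed=config.seed)

    t0 = time.perf_counter()
    if config.paths:
        cohort = _load_blocks(config)
        manifest.log_stage("load", time.perf_counter() - t0)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = simulate_cohort(syn)
        cohort_dir = os.path.join(config.out_dir, "cohort")
        write_cohort(cohort, cohort_dir, write_vcf=False)
        manifest.log_stage("simulate", time.perf_counter() - t0,
                           n_samples=syn.n_samples)
    y = cohort.labels

    t0 = time.perf_counter()
    blocks, qc = preprocess_cohort(cohort, config)
    manifest.qc_reports = qc
    manifest.log_stage(
        "preprocess", time.perf_counter() - t0,
        dims={b.name: [b.n_samples, b.n_features] for b in blocks},
    )

    t0 = time.perf_counter()
    plan = make_splits(len(y), n_splits=config.n_splits,
                       train_frac=config.train_frac,
                       seed=config.seed + SPLIT_SEED_OFFSET)
    manifest.log_stage("splits", time.perf_counter() - t0,
                       n_splits=plan.n_splits)

    t0 = time.perf_counter()
    panel = run_persistence_selection(
        blocks, y, plan, keep_x=config.keep_x,
        n_components=config.n_components,
        threshold=config.persistence_threshold,
    )
    panel_path = os.path.join(config.out_dir, "panel.tsv")
    panel.to_frame().to_csv(panel_path, sep="\t", index=False)
    manifest.checksum(panel_path)
    panel_sets = panel.panel()
    manifest.log_stage(
        "select", time.perf_counter() - t0,
        panel_sizes={k: len(v) for k, v in panel_sets.items()},
    )

    t0 = time.perf_counter()
    scaled = []
    for b in blocks:
        feats = panel_sets.get(b.name, [])
        if not feats:
            continue
        sb, _ = autoscale(b.subset_features(feats))
        scaled.append(sb)
    results = BlockPLSDA(scaled, y, n_components=config.n_components).fit()
    model_path = os.path.join(config.out_dir, "block_model.json")
    with open(model_path, "w") as fh:
        fh.write(results.to_json())
    manifest.checksum(model_path)
    arrow_path = os.path.join(config.out_dir, "arrow_data.tsv")
    results.arrow_data().to_csv(arrow_path, sep="\t", index=False,
                                float_format="%.10g")
    manifest.checksum(arrow_path)
    manifest.log_stage("integrate", time.perf_counter() - t0)

    t0 = time.perf_counter()
    evaluations = {"block": evaluate_over_splits(
        blocks, y, plan, panel_sets, model="block",
        n_components=config.n_components,
    )}
    for b in blocks:
        if panel_sets.get(b.name):
            evaluations[b.name] = evaluate_over_splits(
                blocks, y, plan, panel_sets, model=f"single:{b.name}",
                n_components=config.n_components,
            )
    metrics_path = os.path.join(config.out_dir, "metrics.tsv")
    import pandas as pd
    pd.concat([e.to_frame() for e in evaluations.values()]).to_csv(
        metrics_path, sep="\t", index=False, float_format="%.10g"
    )
    manifest.checksum(metrics_path)
    summary = {
        "majority_baseline": majority_baseline(y),
        "models": {
            name: {
                f"{metric}_comp{k}": {"mean": e.get(metric, k).mean,
                                      "sd": e.get(metric, k).sd}
                for metric in ("accuracy", "auc", "mcc")
                for k in range(1, config.n_components + 1)
            }
            for name, e in evaluations.items()
        },
    }
    summary_path = os.path.join(config.out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    manifest.checksum(summary_path)
    manifest.log_stage("evaluate", time.perf_counter() - t0)

    t0 = time.perf_counter()
    corr = feature_component_correlations(results, scaled)
    circle_path = os.path.join(config.out_dir, "circle_coordinates.tsv")
    corr.to_csv(circle_path, sep="\t", float_format="%.10g")
    manifest.checksum(circle_path)
    assoc = cross_omics_association(corr)
    net = build_network(assoc, threshold=config.network_threshold)
    edges_path = os.path.join(config.out_dir, "network_edges.tsv")
    net.edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
    manifest.checksum(edges_path)
    pooled = pd.concat([sb.to_frame().add_prefix(f"{sb.name}:") for sb in scaled],
                       axis=1)
    row_order, col_order, _ = cluster_heatmap_order(pooled)
    order_path = os.path.join(config.out_dir, "heatmap_order.tsv")
    pd.DataFrame({
        "axis": ["sample"] * len(row_order) + ["feature"] * len(col_order),
        "position": list(range(len(row_order))) + list(range(len(col_order))),
        "index": row_order + col_order,
        "id": [pooled.index[i] for i in row_order]
              + [pooled.columns[i] for i in col_order],
    }).to_csv(order_path, sep="\t", index=False)
    manifest.checksum(order_path)
    manifest.log_stage(
        "interpret", time.perf_counter() - t0,
        network_edges=net.n_edges, average_degree=net.average_degree,
    )

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    manifest.write(manifest_path)
    return manifest
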