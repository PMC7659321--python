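"""End-to-end pipeline orchestration and run provenance.

``run_pipeline`` chains the stages — preprocess -> network modules ->
pathway enrichment features -> PU label expansion -> classifier evaluation
and consensus prediction — writing each stage's artifacts plus a
provenance JSON (parameter hash, seeds, package versions, input hashes).
Re-running with identical inputs and config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, enrichment, io, network, preprocessing, pu
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the reference analysis
    (0.1 raw expression in >= 80% of samples, outlier z < -3, ventilator
    subset, beta = 12 signed, BH alpha 0.05, t = 100 bagging rounds with
    k = |positives|, 0.7/0.8 rate thresholds, 10 CV folds, k-NN grid 1-10).
    """

    # inputs
    expression: str = ""
    metadata: str | None = None
    pathways: str = ""
    receptors: str = ""
    seed_positives: str = ""
    known_negatives: str | None = None
    accept_list: str | None = None
    # preprocess
    min_value: float = 0.1
    min_fraction: float = 0.8
    pseudocount: float = 1.0
    outlier_sd: float = -3.0
    death_class: str | None = "ventilator"
    adjust_factors: tuple = ("batch", "ischemic_bin", "sex", "age_bin")
    # network
    beta: float = 12.0
    signed: bool = True
    corr_method: str = "bicor"
    cut_height: float = 0.995
    min_module_size: int = 30
    merge_height: float = 0.25
    # enrichment
    alpha: float = 0.05
    # PU bagging
    pu_iterations: int = 100
    pu_sample_size: int | None = None  # None -> |seed positives|
    pos_threshold: float = 0.7
    neg_threshold: float = 0.8
    min_oob: int = 10
    # classification
    n_folds: int = 10
    metric_variant: str = "paper"
    tune: bool = True
    rng_seed: int = 7

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "adjust_factors" in d:
            d["adjust_factors"] = tuple(d["adjust_factors"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adjust_factors"] = list(d["adjust_factors"])
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    partition: object
    enrichment: pd.DataFrame
    features: object  # FeatureMatrix
    rates: pd.DataFrame
    labels: object  # LabelSet
    evaluation: dict
    consensus: frozenset
    votes: pd.DataFrame
    filter_report: object
    artifacts: dict = field(default_factory=dict)


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every stage; write artifacts to ``outdir`` when given."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for name in ("expression", "pathways", "receptors", "seed_positives"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config input {name!r} missing or not found: {p!r}")

    def _stage(name):
        logger.info("stage: %s", name)

    # --- preprocess
    _stage("preprocess")
    expr = io.read_expression_tsv(config.expression, config.metadata)
    expr, report = preprocessing.preprocess_expression(
        expr,
        min_value=config.min_value,
        min_fraction=config.min_fraction,
        pseudocount=config.pseudocount,
        sd_cutoff=config.outlier_sd,
        death_class=config.death_class,
        factors=config.adjust_factors,
        adjust=expr.covariates is not None,
    )
    logger.info("preprocess filter counts: %s", report.to_dict())

    # --- network modules
    _stage("netmod")
    corr = (network.bicor if config.corr_method == "bicor" else network.pearson)(
        expr.values.to_numpy(), gene_ids=expr.gene_ids
    )
    adj = network.soft_adjacency(corr, beta=config.beta, signed=config.signed)
    tom = network.tom_similarity(adj)
    partition = network.detect_modules(
        tom,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_height=config.merge_height,
        expr=expr,
    )

    # --- enrichment features
    _stage("enrich")
    gene_sets = io.read_gmt(config.pathways, universe=expr.gene_ids)
    enr = enrichment.enrich_modules(partition, gene_sets, alpha=config.alpha)
    receptors = io.read_gene_list(config.receptors)
    features = enrichment.build_feature_matrix(partition, enr, receptors, alpha=config.alpha)
    logger.info(
        "features: %d receptors x %d pathways (%d unassigned, %d missing)",
        *features.values.shape,
        len(features.excluded_unassigned),
        len(features.excluded_missing),
    )

    # --- PU label expansion
    _stage("pulabel")
    seed_positives = [r for r in io.read_gene_list(config.seed_positives)
                      if r in features.values.index]
    known_negatives = (
        [r for r in io.read_gene_list(config.known_negatives) if r in features.values.index]
        if config.known_negatives
        else []
    )
    accept = io.read_gene_list(config.accept_list) if config.accept_list else None
    rates = pu.pu_bagging(
        features.values,
        seed_positives,
        t=config.pu_iterations,
        k=config.pu_sample_size,
        rng_seed=config.rng_seed,
        min_oob=config.min_oob,
    )
    labels = pu.derive_labels(
        rates,
        pos_threshold=config.pos_threshold,
        neg_threshold=config.neg_threshold,
        accept_list=accept,
        seed_positives=seed_positives,
        known_negatives=known_negatives,
    )

    # --- classification, evaluation, consensus
    _stage("classeval")
    negative_groups = {"inferred": labels.negatives_inferred}
    if labels.negatives_known:
        negative_groups["known"] = labels.negatives_known
    evaluation = classify.evaluate_label_sets(
        features.values,
        labels.positives,
        negative_groups,
        n_folds=config.n_folds,
        rng_seed=config.rng_seed,
        variant=config.metric_variant,
        tune=config.tune,
    )
    specs = {g: {"svm_cost": evaluation[g]["svm_cost"], "knn_k": evaluation[g]["knn_k"]}
             for g in negative_groups}
    models = classify.fit_final_models(
        features.values, labels.positives, negative_groups, specs=specs,
        n_folds=config.n_folds, rng_seed=config.rng_seed,
    )
    unlabeled_ids = [r for r in features.values.index if r in labels.unlabeled]
    consensus, votes = classify.consensus_predict(features.values.loc[unlabeled_ids], models)

    result = PipelineResult(
        expression=expr,
        partition=partition,
        enrichment=enr,
        features=features,
        rates=rates,
        labels=labels,
        evaluation=evaluation,
        consensus=consensus,
        votes=votes,
        filter_report=report,
    )
    if outdir is not None:
        result.artifacts = _write_artifacts(config, result, outdir)
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult, outdir: Path) -> dict:
    cfg_hash = config.content_hash()
    paths = {}

    def _save(name, writer):
        path = outdir / name
        writer(path)
        paths[name] = path

    _save("expression_preprocessed.tsv",
          lambda p: io.write_expression_tsv(result.expression, p))
    part = result.partition

    def _write_modules(p):
        own = [
            part.kme.loc[g, m] if m > 0 else float("nan")
            for g, m in part.module_of_gene.items()
        ]
        pd.DataFrame(
            {"module": part.module_of_gene, "kme_own_module": own}
        ).rename_axis("gene_id").to_csv(p, sep="\t", float_format="%.6g")

    _save("modules.tsv", _write_modules)
    _save("eigengenes.tsv",
          lambda p: part.eigengenes.rename_axis("sample_id").to_csv(p, sep="\t", float_format="%.6g"))
    _save("enrichment.tsv",
          lambda p: result.enrichment.to_csv(p, sep="\t", index=False, float_format="%.6g"))
    _save("features.tsv",
          lambda p: result.features.values.to_csv(p, sep="\t", float_format="%.6g"))
    _save("pu_rates.tsv",
          lambda p: result.rates.to_csv(p, sep="\t", float_format="%.6g"))
    _save("labels.tsv",
          lambda p: result.labels.to_frame().to_csv(p, sep="\t", index=False))
    _save("predictions.tsv",
          lambda p: result.votes.rename_axis("receptor").to_csv(p, sep="\t"))

    def _write_metrics(p):
        payload = {
            group: {
                "svm_cost": res["svm_cost"],
                "knn_k": res["knn_k"],
                "linear_svm": res["linear_svm"].to_dict(),
                "knn": res["knn"].to_dict(),
            }
            for group, res in result.evaluation.items()
        }
        payload["config_hash"] = cfg_hash
        Path(p).write_text(json.dumps(payload, indent=1, default=float))

    _save("metrics.json", _write_metrics)

    def _write_provenance(p):
        prov = {
            "recmet_version": __version__,
            "numpy_version": np.__version__,
            "config": config.to_dict(),
            "config_hash": cfg_hash,
            "rng_seed": config.rng_seed,
            "input_hashes": {
                name: _file_hash(getattr(config, name))
                for name in ("expression", "metadata", "pathways", "receptors",
                             "seed_positives", "known_negatives", "accept_list")
                if getattr(config, name)
            },
            "filter_report": result.filter_report.to_dict(),
            "n_modules": len(part.module_labels),
            "n_consensus_predictions": len(result.consensus),
        }
        Path(p).write_text(json.dumps(prov, indent=1))

    _save("provenance.json", _write_provenance)
    return paths
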