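"""End-to-end orchestration: simulate (or load) -> batch-correct ->
stage-stratified coexpression -> differential expression -> classifier
-> attribution, with one global seed, per-stage logging and a
consolidated report.

Per-module seeds are derived deterministically as
``sha256(f"{global_seed}:{module}") mod 2**31`` so any stage can be
re-run in isolation and reproduce the full run's stream.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import choose_samples, gene_importance, gradient_shap, interaction_importance
from .classifier import ClassifierConfig, evaluate, stratified_split, train_classifier
from .coexpression import (
    correlation_matrix,
    divergence_ratio,
    hierarchical_cluster,
    hub_coupling_summary,
    stage_correlation_table,
    trajectory_table,
)
from .diffexpr import category_summary, differential_expression
from .io import read_annotation, read_expression
from .panel import DEFAULT_HUB, RECEPTOR_GENES, STAGES, hub_targets
from .preprocess import combat_correct, qc_coefficient_of_variation, Standardizer
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger("ddrcoupling.pipeline")

__all__ = ["RunConfig", "run_full_analysis", "derive_seed", "validate_report"]


def derive_seed(global_seed: int, module: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{module}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class RunConfig:
    """Inputs and per-module settings for one pipeline run.

    Exactly one of ``spec`` (a synthetic generator spec) or the
    ``expression_path``/``annotation_path`` pair must be provided.
    """

    spec: SyntheticSpec | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    hub: str = DEFAULT_HUB
    secondary_hub: str = "DDR1"
    stage_order: tuple[str, ...] = STAGES
    apply_combat: bool = True
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    background_n: int = 100
    explained_n: int = 100
    path_samples: int = 200
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.spec is None) == (self.expression_path is None):
            raise ValueError("provide either a SyntheticSpec or expression/annotation paths")
        if self.expression_path is not None and self.annotation_path is None:
            raise ValueError("annotation_path required with expression_path")
        if len(self.stage_order) != 3:
            raise ValueError("stage_order must contain exactly the three stages")

    def hash(self) -> str:
        payload = {
            "spec_seed": None if self.spec is None else self.spec.seed,
            "spec_genes": None if self.spec is None else list(self.spec.genes),
            "expression_path": self.expression_path,
            "annotation_path": self.annotation_path,
            "hub": self.hub,
            "secondary_hub": self.secondary_hub,
            "stage_order": list(self.stage_order),
            "apply_combat": self.apply_combat,
            "classifier_seed": self.classifier.seed,
            "background_n": self.background_n,
            "explained_n": self.explained_n,
            "path_samples": self.path_samples,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage in order and return the consolidated report
    (JSON-serialisable dict).  With ``config.output_dir`` set, the
    report and all tables are also written there."""
    config.validate()

    # -- data -------------------------------------------------------------
    if config.spec is not None:
        spec = config.spec
        spec.seed = derive_seed(config.seed, "synthetic")
        X, ann = generate_dataset(spec)
        logger.info("simulated %d genes x %d samples", *X.shape)
    else:
        X = read_expression(config.expression_path)
        ann = read_annotation(config.annotation_path)
        logger.info("loaded %d genes x %d samples", *X.shape)
    panel = tuple(X.index)
    for h in (config.hub, config.secondary_hub):
        if h not in panel:
            raise ValueError(f"hub {h!r} missing from expression matrix genes")

    # -- preprocess ---------------------------------------------------------
    if config.apply_combat and ann["batch"].nunique() > 1:
        X, _batch_model = combat_correct(X, ann)
        logger.info("batch-corrected %d batches", ann["batch"].nunique())
    qc = qc_coefficient_of_variation(X)
    logger.info("QC: %d/%d genes flagged", int(qc["flagged"].sum()), len(qc))

    # -- coexpression -------------------------------------------------------
    records = pd.concat(
        [stage_correlation_table(X, ann, s) for s in config.stage_order],
        ignore_index=True,
    )
    targets = hub_targets(config.hub, panel)
    summaries = {
        h: hub_coupling_summary(records, h, hub_targets(h, panel), config.stage_order)
        for h in (config.hub, config.secondary_hub)
    }
    divergences = {
        s: divergence_ratio(summaries[config.hub], summaries[config.secondary_hub], s)
        for s in config.stage_order
    }
    hub_pairs = [(config.hub, t) for t in targets]
    trajectories = trajectory_table(records, hub_pairs, stage_order=config.stage_order)
    dendrograms = {
        s: hierarchical_cluster(correlation_matrix(X, ann, s)).to_newick()
        for s in config.stage_order
    }
    logger.info("coexpression: %d records, %d trajectories", len(records), len(trajectories))

    # -- differential expression -------------------------------------------
    de = differential_expression(X, ann, config.stage_order)
    fold_col = f"fold_{config.stage_order[0]}_vs_{config.stage_order[-1]}"
    ratio_col = f"ratio_log2_means_{config.stage_order[0]}_vs_{config.stage_order[-1]}"
    cats = category_summary(de, fold_column=fold_col)
    cats_ratio = category_summary(de, fold_column=ratio_col)
    logger.info("differential expression: %d genes", len(de))

    # -- classifier ---------------------------------------------------------
    split_seed = derive_seed(config.seed, "split")
    train_ids, val_ids, test_ids = stratified_split(
        ann, config.classifier.split_fractions, split_seed
    )
    std = Standardizer.fit(X[train_ids])
    stage_idx = {s: i for i, s in enumerate(config.stage_order)}
    labels = ann.set_index("sample_id")["stage"].map(stage_idx)
    clf_config = config.classifier
    clf_config.seed = derive_seed(config.seed, "classifier")
    model = train_classifier(
        clf_config,
        std.transform(X[train_ids]).T.to_numpy(),
        labels[train_ids].to_numpy(),
        std.transform(X[val_ids]).T.to_numpy(),
        labels[val_ids].to_numpy(),
    )
    metrics = evaluate(
        model,
        std.transform(X[test_ids]).T.to_numpy(),
        labels[test_ids].to_numpy(),
        config.stage_order,
    )
    logger.info("classifier: test accuracy %.4f", metrics.accuracy)

    # -- attribution --------------------------------------------------------
    attr_seed = derive_seed(config.seed, "attribution")
    bg_ids = choose_samples(train_ids, config.background_n, attr_seed)
    ex_ids = choose_samples(test_ids, config.explained_n, attr_seed + 1)
    result = gradient_shap(
        model,
        std.transform(X[bg_ids]).T.to_numpy(),
        std.transform(X[ex_ids]).T.to_numpy(),
        path_samples=config.path_samples,
        seed=attr_seed,
        genes=panel,
        class_names=config.stage_order,
        background_ids=tuple(bg_ids),
        explained_ids=tuple(ex_ids),
    )
    carcinoma = config.stage_order[-1]
    importance = gene_importance(result, carcinoma)
    partners = tuple(g for g in panel if g != config.hub)
    interactions = interaction_importance(result, config.hub, partners, carcinoma)
    logger.info("attribution: top interaction %s", interactions["pair"].iloc[0])

    # -- convergence --------------------------------------------------------
    top_delta = trajectories.loc[trajectories["delta_overall"].idxmax()]
    top_delta_pair = f"{top_delta['gene_a']}-{top_delta['gene_b']}"
    de_targets = de.loc[list(targets)]
    top_fold_gene = de_targets[ratio_col].idxmax()
    top_interaction_pair = interactions["pair"].iloc[0]
    converged = (
        top_delta["gene_b"] == top_fold_gene
        and top_interaction_pair == f"{config.hub}-{top_fold_gene}"
        and top_delta_pair == top_interaction_pair
    )

    report = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": int(config.seed),
            "package_version": __version__,
        },
        "qc": {
            "n_flagged": int(qc["flagged"].sum()),
            "flagged_genes": list(qc.index[qc["flagged"]]),
        },
        "hub_summaries": {
            h: {
                "mean_r2_by_stage": s.mean_r2_by_stage,
                "overall_fold": s.overall_fold,
                "per_transition_fold": s.per_transition_fold,
            }
            for h, s in summaries.items()
        },
        "divergence_ratios": divergences,
        "trajectories": trajectories.to_dict(orient="records"),
        "dendrograms": dendrograms,
        "differential_expression": de.reset_index().to_dict(orient="records"),
        "category_summary": {
            "fold_2_pow_delta": cats["mean_fold"].to_dict(),
            "ratio_log2_means": cats_ratio["mean_fold"].to_dict(),
        },
        "classifier": {
            "accuracy": metrics.accuracy,
            "precision": metrics.precision,
            "recall": metrics.recall,
            "f1": metrics.f1,
            "auc": metrics.auc,
            "confusion": metrics.confusion.to_dict(),
            "n_train": len(train_ids),
            "n_val": len(val_ids),
            "n_test": len(test_ids),
            "epochs": len(model.history["train_loss"]),
        },
        "attribution": {
            "gene_importance": importance.to_dict(orient="records"),
            "interaction_importance": interactions.to_dict(orient="records"),
            "top_gap_pct": interactions.attrs["top_gap_pct"],
        },
        "convergence": {
            "top_delta_pair": top_delta_pair,
            "top_fold_gene": str(top_fold_gene),
            "top_interaction_pair": top_interaction_pair,
            "converged": bool(converged),
        },
    }
    validate_report(report)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.10g")
        trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False, float_format="%.10g")
        de.to_csv(out / "differential_expression.tsv", sep="\t", float_format="%.10g")
        importance.to_csv(out / "gene_importance.tsv", sep="\t", index=False, float_format="%.10g")
        interactions.to_csv(out / "interaction_importance.tsv", sep="\t", index=False, float_format="%.10g")
        result.to_long_frame().to_csv(out / "shap_values.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# schema validation (minimal subset of JSON Schema)


def _schema() -> dict:
    text = resources.files("ddrcoupling").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Check the report against the checked-in schema (types and
    required keys, recursively)."""

    def check(node: dict, schema: dict, path: str) -> None:
        t = schema.get("type")
        if t == "object":
            if not isinstance(node, dict):
                raise ValueError(f"{path}: expected object")
            for key in schema.get("required", []):
                if key not in node:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in schema.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{path}.{key}")
        elif t == "array":
            if not isinstance(node, list):
                raise ValueError(f"{path}: expected array")
        elif t == "string":
            if not isinstance(node, str):
                raise ValueError(f"{path}: expected string")
        elif t == "integer":
            if not isinstance(node, int):
                raise ValueError(f"{path}: expected integer")

    check(report, _schema(), "report")
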