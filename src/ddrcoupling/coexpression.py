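"""Stage-stratified pairwise coupling analysis.

For each disease stage the module computes Pearson correlations for all
unordered gene pairs (91 for the 14-gene panel), converts them to
coefficients of determination R^2, controls the false discovery rate
with Benjamini-Hochberg within the stage, summarises hub (DDR receptor)
coupling as the mean R^2 over its 12 designated targets, derives
per-pair coupling trajectories across the stage order with deltas,
fold-ratios and a kinetic class, and clusters genes by the
sign-symmetric correlation distance d = 1 - |r| with average linkage.

Kinetic classes follow the two observed archetypes: "de_novo"
activation from a near-zero baseline to substantial carcinoma coupling,
"progressive" monotone strengthening from a detectable baseline,
"declining" when carcinoma coupling falls below baseline, and "flat"
otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .panel import STAGES

__all__ = [
    "pearson_r",
    "bh_fdr",
    "stage_correlation_table",
    "correlation_matrix",
    "HubSummary",
    "hub_coupling_summary",
    "divergence_ratio",
    "CouplingTrajectory",
    "coupling_trajectory",
    "trajectory_table",
    "Dendrogram",
    "hierarchical_cluster",
]

#: Fold ratios with a denominator R^2 below this floor are reported as
#: undefined (NaN) -- near-zero baselines make ratios numerically wild.
FOLD_DENOMINATOR_FLOOR = 1e-3

#: Baseline R^2 below this is "near zero" for kinetic classification.
NEAR_ZERO_FLOOR = 0.05

#: Carcinoma R^2 at or above this counts as substantial de novo coupling.
DE_NOVO_CARCINOMA_MIN = 0.3


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value from the exact
    t-test with n-2 degrees of freedom under the null of zero
    correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"correlation undefined: vector {name} is constant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage_correlation_table(
    X: pd.DataFrame, annotation: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """One row per unordered gene pair for one stage.

    Pair orientation follows the fixed gene ordering of ``X``; BH is
    applied across all pairs within the stage.  Columns:
    ``gene_a, gene_b, stage, r, r2, p, q, n``.
    """
    ids = annotation.loc[annotation["stage"] == stage, "sample_id"]
    if len(ids) == 0:
        raise ValueError(f"stage {stage!r} absent from annotations")
    if len(ids) < 3:
        raise ValueError(f"stage {stage!r} has fewer than 3 samples")
    sub = X[list(ids)]
    genes = list(X.index)
    rows = []
    for a, b in itertools.combinations(genes, 2):
        r, p = pearson_r(sub.loc[a].to_numpy(), sub.loc[b].to_numpy())
        rows.append((a, b, stage, r, r * r, p, len(ids)))
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "stage", "r", "r2", "p", "n"]
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table[["gene_a", "gene_b", "stage", "r", "r2", "p", "q", "n"]]


def correlation_matrix(
    X: pd.DataFrame, annotation: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Symmetric gene x gene Pearson correlation matrix for one stage."""
    ids = annotation.loc[annotation["stage"] == stage, "sample_id"]
    if len(ids) < 3:
        raise ValueError(f"stage {stage!r} has fewer than 3 samples")
    sub = X[list(ids)].to_numpy(float)
    r = np.corrcoef(sub)
    return pd.DataFrame(r, index=X.index, columns=X.index)


# ---------------------------------------------------------------------------
# hub summaries


@dataclass
class HubSummary:
    """Mean coupling of one DDR hub to its designated target set."""

    hub: str
    targets: tuple[str, ...]
    mean_r2_by_stage: dict[str, float]
    overall_fold: float
    per_transition_fold: dict[str, float]


def hub_coupling_summary(
    records: pd.DataFrame,
    hub: str,
    targets: tuple[str, ...],
    stage_order: tuple[str, ...] = STAGES,
) -> HubSummary:
    """Arithmetic mean of hub-target R^2 per stage and stage-mean fold
    ratios (overall = last/first stage).  Every (hub, target, stage)
    record must be present.  Folds over a zero denominator are NaN."""
    means: dict[str, float] = {}
    for stage in stage_order:
        sub = records[records["stage"] == stage]
        r2s = []
        for t in targets:
            hit = sub[
                ((sub["gene_a"] == hub) & (sub["gene_b"] == t))
                | ((sub["gene_a"] == t) & (sub["gene_b"] == hub))
            ]
            if len(hit) != 1:
                raise ValueError(f"missing correlation record for ({hub}, {t}, {stage})")
            r2s.append(float(hit["r2"].iloc[0]))
        means[stage] = float(np.mean(r2s))
    first, last = stage_order[0], stage_order[-1]
    overall = means[last] / means[first] if means[first] > 0 else float("nan")
    transitions = {}
    for s_from, s_to in zip(stage_order[:-1], stage_order[1:]):
        transitions[f"{s_from}->{s_to}"] = (
            means[s_to] / means[s_from] if means[s_from] > 0 else float("nan")
        )
    return HubSummary(
        hub=hub,
        targets=tuple(targets),
        mean_r2_by_stage=means,
        overall_fold=overall,
        per_transition_fold=transitions,
    )


def divergence_ratio(summary_a: HubSummary, summary_b: HubSummary, stage: str) -> float:
    """Ratio of two hubs' mean coupling strength in one stage (a/b)."""
    denom = summary_b.mean_r2_by_stage[stage]
    return summary_a.mean_r2_by_stage[stage] / denom if denom > 0 else float("nan")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class CouplingTrajectory:
    """Per-pair R^2 across the ordered stages with deltas, folds and a
    kinetic class."""

    gene_a: str
    gene_b: str
    r_squared_by_stage: dict[str, float]
    delta_r2: dict[str, float]
    fold_r2: dict[str, float]
    kinetic_class: str


def _classify(
    r2s: list[float], near_zero_floor: float
) -> str:
    first, last = r2s[0], r2s[-1]
    if first < near_zero_floor and last >= DE_NOVO_CARCINOMA_MIN:
        return "de_novo"
    if first >= near_zero_floor and all(b > a for a, b in zip(r2s, r2s[1:])):
        return "progressive"
    if last < first:
        return "declining"
    return "flat"


def coupling_trajectory(
    records: pd.DataFrame,
    pair: tuple[str, str],
    near_zero_floor: float = NEAR_ZERO_FLOOR,
    stage_order: tuple[str, ...] = STAGES,
) -> CouplingTrajectory:
    """Trajectory of one unordered pair across all stages in
    ``records`` (long table with a ``stage`` column covering every stage
    of ``stage_order``)."""
    a, b = pair
    r2_by_stage: dict[str, float] = {}
    for stage in stage_order:
        sub = records[records["stage"] == stage]
        hit = sub[
            ((sub["gene_a"] == a) & (sub["gene_b"] == b))
            | ((sub["gene_a"] == b) & (sub["gene_b"] == a))
        ]
        if len(hit) != 1:
            raise ValueError(f"pair {pair} missing in stage {stage!r}")
        r2_by_stage[stage] = float(hit["r2"].iloc[0])

    r2s = [r2_by_stage[s] for s in stage_order]
    deltas, folds = {}, {}
    for s_from, s_to in zip(stage_order[:-1], stage_order[1:]):
        key = f"{s_from}->{s_to}"
        deltas[key] = r2_by_stage[s_to] - r2_by_stage[s_from]
        folds[key] = (
            r2_by_stage[s_to] / r2_by_stage[s_from]
            if r2_by_stage[s_from] >= FOLD_DENOMINATOR_FLOOR
            else float("nan")
        )
    overall = f"{stage_order[0]}->{stage_order[-1]}"
    deltas[overall] = r2s[-1] - r2s[0]
    folds[overall] = r2s[-1] / r2s[0] if r2s[0] >= FOLD_DENOMINATOR_FLOOR else float("nan")
    return CouplingTrajectory(
        gene_a=a,
        gene_b=b,
        r_squared_by_stage=r2_by_stage,
        delta_r2=deltas,
        fold_r2=folds,
        kinetic_class=_classify(r2s, near_zero_floor),
    )


def trajectory_table(
    records: pd.DataFrame,
    pairs: list[tuple[str, str]],
    near_zero_floor: float = NEAR_ZERO_FLOOR,
    stage_order: tuple[str, ...] = STAGES,
) -> pd.DataFrame:
    """Long trajectory summary for many pairs, one row per pair."""
    rows = []
    overall = f"{stage_order[0]}->{stage_order[-1]}"
    for pair in pairs:
        t = coupling_trajectory(records, pair, near_zero_floor, stage_order)
        row = {"gene_a": t.gene_a, "gene_b": t.gene_b}
        for s in stage_order:
            row[f"r2_{s}"] = t.r_squared_by_stage[s]
        for k, v in t.delta_r2.items():
            row[f"delta_{k}"] = v
        for k, v in t.fold_r2.items():
            row[f"fold_{k}"] = v
        row["kinetic_class"] = t.kinetic_class
        row["delta_overall"] = t.delta_r2[overall]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class Dendrogram:
    """Average-linkage tree over the correlation distance d = 1 - |r|."""

    labels: tuple[str, ...]
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray = field(repr=False)

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(corr: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering of genes on d = 1 - |r|.

    Requires a square symmetric matrix with unit diagonal; the absolute
    value treats positive and negative coupling symmetrically."""
    values = corr.to_numpy(float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    dist = 1.0 - np.abs(values)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(
        labels=tuple(corr.index),
        merge_heights=Z[:, 2].copy(),
        linkage_matrix=Z,
    )
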