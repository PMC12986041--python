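"""Stage-wise differential expression: one-way ANOVA, Tukey HSD post hoc
comparisons, fold-changes and functional-category summaries.

The F statistic is the ratio of between-stage to within-stage mean
squares on (k-1, N-k) degrees of freedom; post hoc contrasts use the
Studentized range statistic

    q = |mean_1 - mean_2| / sqrt(MSW/2 * (1/n_1 + 1/n_2))

(the Tukey-Kramer form, valid for unbalanced groups).  Fold-changes
convert log2 mean differences back to the linear scale as 2^(delta);
because published per-gene folds in this literature are sometimes plain
ratios of log2 means, that ratio is reported alongside.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GENE_CATEGORIES, STAGES
from .coexpression import bh_fdr

__all__ = [
    "anova_oneway",
    "tukey_hsd",
    "fold_change",
    "differential_expression",
    "category_summary",
]


def _group_arrays(values_by_stage: dict[str, np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(v, float) for v in values_by_stage.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(values_by_stage, groups):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    return groups


def _ms_within(groups: list[np.ndarray]) -> tuple[float, int]:
    n_total = sum(len(g) for g in groups)
    df = n_total - len(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return ssw / df, df


def anova_oneway(values_by_stage: dict[str, np.ndarray]) -> tuple[float, float]:
    """F and upper-tail p on (k-1, N-k) degrees of freedom.

    Degenerate inputs (zero within-group variance) return ``(inf, 0.0)``
    when the group means differ and ``(nan, nan)`` when they are all
    equal; callers flag rather than fail.
    """
    groups = _group_arrays(values_by_stage)
    msw, _ = _ms_within(groups)
    means = [g.mean() for g in groups]
    if msw == 0.0:
        if np.ptp(means) == 0:
            return float("nan"), float("nan")
        return float("inf"), 0.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(values_by_stage: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs comparisons under the Studentized range law with k
    groups and N-k error degrees of freedom.

    Returns one row per unordered stage pair with the q statistic, the
    Tukey-adjusted p and the log2 mean difference (second minus first).
    """
    groups = _group_arrays(values_by_stage)
    names = list(values_by_stage)
    msw, _ = _ms_within(groups)
    res = stats.tukey_hsd(*groups) if msw > 0 else None
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        diff = groups[j].mean() - groups[i].mean()
        if msw > 0:
            se = math.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            q = abs(diff) / se
            p = float(res.pvalue[i, j])
        elif diff == 0:
            q, p = 0.0, 1.0
        else:
            q, p = float("inf"), 0.0
        rows.append((a, b, diff, q, p))
    return pd.DataFrame(
        rows, columns=["stage_a", "stage_b", "mean_diff", "q", "p_adj"]
    )


def fold_change(mean_from: float, mean_to: float) -> float:
    """2^(mean_to - mean_from): linear fold from log2 means."""
    return float(2.0 ** (mean_to - mean_from))


def differential_expression(
    X: pd.DataFrame,
    annotation: pd.DataFrame,
    stage_order: tuple[str, ...] = STAGES,
    posthoc_q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene ANOVA across stages with BH correction across genes and
    Tukey post hoc contrasts for genes passing the FDR threshold.

    Per stage pair the table carries the Tukey-adjusted p, the 2^delta
    fold-change and the plain ratio of log2 means; post hoc columns stay
    NaN for genes whose overall ANOVA q misses the threshold.
    """
    ann = annotation.set_index("sample_id")
    by_stage_ids = {
        s: annotation.loc[annotation["stage"] == s, "sample_id"].tolist()
        for s in stage_order
    }
    for s, ids in by_stage_ids.items():
        if len(ids) < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 samples")

    rows = []
    for gene in X.index:
        vals = {s: X.loc[gene, ids].to_numpy(float) for s, ids in by_stage_ids.items()}
        F, p = anova_oneway(vals)
        row: dict[str, float | str | bool] = {"gene": gene, "F": F, "p": p}
        row["degenerate"] = not np.isfinite(F)
        for s in stage_order:
            row[f"mean_{s}"] = vals[s].mean()
            row[f"n_{s}"] = len(vals[s])
        rows.append((row, vals))

    table = pd.DataFrame([r for r, _ in rows]).set_index("gene")
    finite = table["p"].notna()
    q = np.full(len(table), np.nan)
    q[finite.to_numpy()] = bh_fdr(table.loc[finite, "p"].to_numpy())
    table["q"] = q

    pair_cols: dict[str, dict[str, float]] = {}
    for (row, vals) in rows:
        gene = row["gene"]
        significant = np.isfinite(table.loc[gene, "q"]) and table.loc[gene, "q"] < posthoc_q_threshold
        posthoc = tukey_hsd(vals) if significant else None
        for a, b in itertools.combinations(stage_order, 2):
            key = f"{a}_vs_{b}"
            cols = pair_cols.setdefault(gene, {})
            ma, mb = float(np.mean(vals[a])), float(np.mean(vals[b]))
            cols[f"fold_{key}"] = fold_change(ma, mb)
            cols[f"ratio_log2_means_{key}"] = mb / ma if ma != 0 else float("nan")
            if posthoc is not None:
                hit = posthoc[(posthoc["stage_a"] == a) & (posthoc["stage_b"] == b)]
                cols[f"tukey_p_{key}"] = float(hit["p_adj"].iloc[0])
                cols[f"tukey_q_{key}"] = float(hit["q"].iloc[0])
            else:
                cols[f"tukey_p_{key}"] = float("nan")
                cols[f"tukey_q_{key}"] = float("nan")
    extra = pd.DataFrame(pair_cols).T
    return table.join(extra)


def category_summary(
    records: pd.DataFrame,
    category_map: dict[str, str] | None = None,
    fold_column: str = "fold_normal_vs_carcinoma",
) -> pd.DataFrame:
    """Arithmetic mean of normal->carcinoma fold-changes per functional
    category (receptor / collagen / mmp).  Every gene must be
    categorized."""
    cats = category_map if category_map is not None else GENE_CATEGORIES
    missing = [g for g in records.index if g not in cats]
    if missing:
        raise ValueError(f"uncategorized genes: {missing}")
    if fold_column not in records.columns:
        raise ValueError(f"column {fold_column!r} not in records")
    out = (
        records[fold_column]
        .groupby([cats[g] for g in records.index])
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_fold", "count": "n_genes"})
    )
    out.index.name = "category"
    return out
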