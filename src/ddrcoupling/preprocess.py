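"""Probe aggregation, empirical-Bayes batch correction, expression QC
and train-statistics standardization.

The batch model is the location/scale form

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

with additive (gamma) and multiplicative (delta) per-(gene, batch)
effects estimated by parametric empirical-Bayes shrinkage (normal prior
on gamma, inverse-gamma on delta, moment-matched) and removed while the
biological covariate -- disease stage -- is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# probe-to-gene aggregation


@dataclass
class AggregationReport:
    """Bookkeeping of what aggregation dropped."""

    multi_gene_probes: list[str] = field(default_factory=list)
    genes_without_probes: list[str] = field(default_factory=list)


def read_probe_map(
    path: str | Path, multi_gene_delimiter: str = "///"
) -> dict[str, frozenset[str]]:
    """Two-column TSV ``probe_id<TAB>gene_symbol``; entries naming several
    genes use the declared delimiter."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs columns (probe_id, gene_symbol)")
    probe_col, gene_col = df.columns[:2]
    out: dict[str, frozenset[str]] = {}
    for probe, symbols in zip(df[probe_col], df[gene_col]):
        genes = frozenset(s.strip() for s in str(symbols).split(multi_gene_delimiter))
        out[str(probe)] = genes
    return out


def aggregate_probes(
    probe_matrix: pd.DataFrame, probe_map: dict[str, frozenset[str] | set[str]]
) -> tuple[pd.DataFrame, AggregationReport]:
    """Collapse a probe x sample matrix to gene level.

    Probes mapping to more than one gene are excluded (ambiguity);
    multiple probes mapping to the same gene are averaged element-wise.
    Genes present in the map but left with zero surviving probes are
    recorded in the report, not raised.
    """
    missing = [p for p in probe_matrix.index if p not in probe_map]
    if missing:
        raise ValueError(f"probes absent from probe_map: {missing[:5]}")

    report = AggregationReport()
    gene_rows: dict[str, list[str]] = {}
    gene_order: list[str] = []
    for genes in probe_map.values():
        for g in sorted(genes):
            if g not in gene_rows:
                gene_rows[g] = []
                gene_order.append(g)
    for probe in probe_matrix.index:
        genes = probe_map[probe]
        if len(genes) != 1:
            report.multi_gene_probes.append(probe)
            continue
        gene_rows[next(iter(genes))].append(probe)

    rows, kept_genes = [], []
    for gene in gene_order:
        probes = gene_rows[gene]
        if not probes:
            report.genes_without_probes.append(gene)
            continue
        rows.append(probe_matrix.loc[probes].mean(axis=0))
        kept_genes.append(gene)
    out = pd.DataFrame(rows, index=kept_genes, columns=probe_matrix.columns)
    out.index.name = "gene_id"
    return out, report


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class BatchModel:
    """Fitted batch-correction model (per-gene location/scale estimates)."""

    overall_mean: pd.Series
    stage_coefficients: pd.DataFrame
    additive_batch: pd.DataFrame
    multiplicative_batch: pd.DataFrame
    prior_parameters: dict[str, dict[str, float]]
    uncorrected_genes: list[str] = field(default_factory=list)


def combat_correct(
    X: pd.DataFrame,
    annotation: pd.DataFrame,
    parametric: bool = True,
    max_iter: int = 200,
    conv: float = 1e-6,
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove batch effects while preserving stage-associated signal.

    Standard location/scale algorithm: fit a gene-wise linear model with
    a stage design, standardize residuals against the pooled variance,
    shrink per-batch additive/multiplicative effect estimates with
    moment-matched parametric priors (normal for gamma, inverse-gamma
    for delta), adjust, and back-transform with the stage coefficients
    added back.

    Genes with zero residual variance are returned uncorrected and
    flagged on the model.  A single batch yields the identity transform
    with a warning.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB mode is implemented")
    ann = annotation.set_index("sample_id").loc[list(X.columns)]
    batches = ann["batch"].to_numpy()
    stages = ann["stage"].to_numpy()
    batch_levels = list(pd.unique(batches))
    stage_levels = list(pd.unique(stages))

    if len(batch_levels) < 2:
        warnings.warn("single batch: ComBat is the identity transform")
        model = BatchModel(
            overall_mean=X.mean(axis=1),
            stage_coefficients=pd.DataFrame(index=X.index),
            additive_batch=pd.DataFrame(0.0, index=X.index, columns=batch_levels),
            multiplicative_batch=pd.DataFrame(1.0, index=X.index, columns=batch_levels),
            prior_parameters={},
        )
        return X.copy(), model
    counts = pd.Series(batches).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

    Y = X.to_numpy(float)  # genes x samples
    n_samples = Y.shape[1]
    batch_onehot = np.column_stack([(batches == b).astype(float) for b in batch_levels])
    cov = np.column_stack(
        [(stages == s).astype(float) for s in stage_levels[1:]]
    )  # reference coding on the first observed stage
    design = np.column_stack([batch_onehot, cov]) if cov.size else batch_onehot

    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # params x genes
    n_batch = len(batch_levels)
    batch_frac = np.array([np.mean(batches == b) for b in batch_levels])
    grand_mean = batch_frac @ B_hat[:n_batch]  # per gene
    stand_mean = grand_mean[None, :] + (cov @ B_hat[n_batch:] if cov.size else 0.0)
    stand_mean = stand_mean.T if cov.size else np.tile(grand_mean[:, None], (1, n_samples))
    # residual variance pooled over all samples (n denominator)
    resid = Y - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)

    degenerate = var_pooled <= 1e-12
    safe_var = np.where(degenerate, 1.0, var_pooled)
    Z = (Y - stand_mean) / np.sqrt(safe_var)[:, None]

    gamma_star = np.zeros((len(X.index), n_batch))
    delta_star = np.ones((len(X.index), n_batch))
    priors: dict[str, dict[str, float]] = {}
    for bi, b in enumerate(batch_levels):
        cols = batches == b
        n_b = cols.sum()
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        m, s2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        priors[b] = {
            "gamma_bar": gamma_bar,
            "tau2": tau2,
            "a_prior": a_prior,
            "b_prior": b_prior,
        }
        g_old, d_old = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[:, bi] = g_old
        delta_star[:, bi] = d_old

    Z_adj = Z.copy()
    for bi, b in enumerate(batch_levels):
        cols = batches == b
        Z_adj[:, cols] = (Z[:, cols] - gamma_star[:, bi][:, None]) / np.sqrt(
            delta_star[:, bi]
        )[:, None]
    Y_adj = Z_adj * np.sqrt(safe_var)[:, None] + stand_mean
    Y_adj[degenerate] = Y[degenerate]  # flagged, left uncorrected

    corrected = pd.DataFrame(Y_adj, index=X.index, columns=X.columns)
    stage_coef = pd.DataFrame(
        B_hat[n_batch:].T, index=X.index, columns=stage_levels[1:]
    )
    model = BatchModel(
        overall_mean=pd.Series(grand_mean, index=X.index),
        stage_coefficients=stage_coef,
        additive_batch=pd.DataFrame(gamma_star, index=X.index, columns=batch_levels),
        multiplicative_batch=pd.DataFrame(
            delta_star, index=X.index, columns=batch_levels
        ),
        prior_parameters=priors,
        uncorrected_genes=list(X.index[degenerate]),
    )
    return corrected, model


def batch_correction_diagnostic(
    X: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, float]:
    """Silhouette of the samples grouped by batch versus by stage.

    After a successful correction the batch silhouette should sit near
    (or below) zero while the stage silhouette stays positive; reported
    as a diagnostic only, with no pass/fail threshold.
    """
    from sklearn.metrics import silhouette_score

    ann = annotation.set_index("sample_id").loc[list(X.columns)]
    samples = X.to_numpy(float).T
    out: dict[str, float] = {}
    for label in ("batch", "stage"):
        groups = ann[label].to_numpy()
        if len(pd.unique(groups)) < 2:
            out[f"silhouette_by_{label}"] = float("nan")
        else:
            out[f"silhouette_by_{label}"] = float(silhouette_score(samples, groups))
    return out


# ---------------------------------------------------------------------------
# QC


def qc_coefficient_of_variation(X: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Per-gene CV = sd/mean on the log2 values (n-1 denominator).

    Report-only: genes with CV at or below the threshold (or undefined
    CV from a zero mean) are flagged, never removed.
    """
    if X.empty:
        raise ValueError("empty expression matrix")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(mean != 0, np.nan)
    report = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    report["flagged"] = cv.isna() | (cv <= threshold)
    return report


# ---------------------------------------------------------------------------
# standardization (train statistics only)


@dataclass
class Standardizer:
    """Per-gene z-scoring with statistics frozen on the training samples."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, X_train: pd.DataFrame) -> "Standardizer":
        means = X_train.mean(axis=1)
        sds = X_train.std(axis=1, ddof=1)
        zero = sds[sds == 0]
        if len(zero):
            raise ValueError(f"zero training variance for genes: {list(zero.index)}")
        return cls(means=means, sds=sds)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.sub(self.means, axis=0).div(self.sds, axis=0)

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z.mul(self.sds, axis=0).add(self.means, axis=0)


def fit_standardizer(X_train: pd.DataFrame) -> Standardizer:
    return Standardizer.fit(X_train)


def apply_standardizer(standardizer: Standardizer, X: pd.DataFrame) -> pd.DataFrame:
    return standardizer.transform(X)
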