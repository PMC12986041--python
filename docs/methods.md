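# Methods

This note documents the models, defaults and numerical choices behind
`ddrcoupling`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort generator

**Model.** Within each disease stage *s* the hub receptor (DDR2 by
default) is drawn i.i.d. normal with stage mean μ_h(s) and variance
σ_h²(s). Every other panel gene *t* is a linear function of the hub
plus independent normal noise:

    t = a(t, s) + β(t, s)·h + ε,   ε ~ N(0, σ_ε²(t, s))

with the slope solved from the planted coefficient of determination,
β = √( R²/(1−R²) · σ_ε²/σ_h² ), so the planted R² is exact in
expectation, and the intercept chosen so the gene's stage mean is
exact. The single-latent-hub construction is the simplest mechanism
with exactly plantable pairwise R²; a side effect is that target–target
and DDR1–target correlations are products of the hub paths
(r_{t1,t2} = r_{h,t1}·r_{h,t2}), which is how the weak, declining DDR1
coupling is produced: DDR1 is a 13th "target" whose hub coupling
(0.211 → 0.090 → 0.045) is chosen so its implied mean target R²
reproduces the reported 0.031 → 0.021 → 0.017.

**Defaults.** Stage sizes are 158/170/352 (normal/adenoma/carcinoma).
Stage means use the published per-gene values where printed (DDR2
7.21 → 5.74 → 6.57; COL11A1 3.61 → 4.84 → 7.18; MMP11 5.28 → 5.83 →
7.85) and otherwise a baseline typical of log2 microarray intensities
with the carcinoma/normal ratio of log2 means matching the published
per-gene fold (e.g. MMP7 1.94, MMP1 1.80, MMP2 1.03). Planted hub R²
uses the five published trajectories (COL11A1, COL5A2, MMP2, COL1A1,
MMP11); the remaining seven targets are fixed once so that the
12-target per-stage means equal the reported 0.147 / 0.234 / 0.380
exactly. Per-gene within-stage variances are constant across stages and
were chosen once so that every gene's pooled coefficient of variation
exceeds 0.2 (the cohort's stated dynamic-range property): genes with
large stage shifts inherit most of their pooled variance from the
between-stage component and keep tight within-stage spread (σ ≈ 0.95
for COL11A1/MMP1/MMP7/MMP9), while flat, highly expressed genes (DDR1,
MMP2, FN1) need σ ≈ 1.9–2.2. These constants live in
`synthetic.DEFAULT_*` and are not tuning knobs.

**Batch effects.** Five pseudo-batches, assigned round-robin within
stage so batch and stage are never confounded. Effects follow the
location/scale form: per batch an additive shift γ ∈ {−0.6, −0.3, 0,
0.3, 0.6} and a residual variance scale δ ∈ {0.6, 0.8, 1.0, 1.25, 1.6},
uniform across genes by default (per-(gene, batch) values are
supported). Because both members of a pair are scaled by the same √δ
within a batch, within-batch correlations are untouched; pooled
correlations are mildly distorted until correction.

**Bimodality (optional, off by default).** MMP7 and MMP1 can receive a
zero-mean two-component normal mixture on their residual (weight 0.45,
separation 1.6 log2 units); the between-component variance is carved
out of the gene's noise variance so the planted R² and total variance
are unchanged.

**Randomness.** One integer seed feeds a `SeedSequence`; per-gene
sub-streams are spawned deterministically, so adding a gene does not
perturb the draws of the others and identical specs are bit-identical.

**What is not emulated.** Probe-level array noise (inputs are assumed
RMA-normalized, log2), heavy-tailed or skewed marginals beyond the
optional mixture, dataset-specific sample overlap (paired
normal/adenoma biopsies), cell-type composition shifts, and any
nonlinearity in gene–gene relations. Tests passing on this generator
show the *pipeline* is correct and calibrated under its assumptions,
not that the biological findings hold on real arrays.

## Batch correction

Parametric empirical-Bayes location/scale correction: a gene-wise
linear model with batch indicators plus a stage design is fitted by
least squares; residuals are standardized by the pooled per-gene
variance (n denominator); per-batch additive (γ̂) and multiplicative
(δ̂, n−1 denominator) effects are shrunk with moment-matched priors
(normal for γ, inverse-gamma for δ) via the standard fixed-point
iteration (relative tolerance 1e-6, cap 200 iterations); adjusted
residuals are back-transformed with the stage effects restored. Genes
with vanishing residual variance are returned unchanged and flagged;
a single batch yields the identity with a warning. The implementation
agrees with `sva::ComBat` (parametric) to ~1e-6 on shared fixtures —
the R routine is used as a cross-check oracle in one test, never as the
implementation. Exact idempotency does not hold (a second pass
re-estimates small shrinkage-noise effects); the test asserts the
second pass moves values by <5% of the first. A
`batch_correction_diagnostic` reports sample silhouettes grouped by
batch versus by stage — after a good correction the batch silhouette
collapses toward zero while the stage silhouette survives — as a
diagnostic only, with no pass/fail threshold.

## Coexpression

Pearson r and the two-sided t-test p (t = r√((n−2)/(1−r²)), n−2 df) are
computed per stage for all 91 unordered panel pairs, oriented by the
fixed panel order. BH is applied within each stage across all 91 pairs,
including the DDR1–DDR2 pair; hub summaries then average R² over
exactly the 12 non-receptor targets. Trajectories report per-transition
and overall ΔR² and fold ratios; fold ratios with a denominator R²
below 1e-3 are reported as NaN (near-zero baselines make ratios
explode — the 0.549/0.006 ≈ 91.5 "activation ratio" is reported as a
derived quantity, not a trajectory fold). Kinetic classes: *de novo*
if baseline R² < 0.05 and carcinoma R² ≥ 0.3; *progressive* if
strictly increasing from a baseline ≥ 0.05; *declining* if carcinoma <
baseline; *flat* otherwise. The 0.05 floor sits below the single-pair
significance threshold at the cohort's smallest stage size.
Average-linkage clustering runs on d = 1 − |r|; merge heights are
tie-invariant and are what tests assert, while tie *ordering* follows
the linkage routine's deterministic internal rule. Dendrograms
serialize to Newick with half the merge height as branch length.

## Differential expression

One-way ANOVA per gene on (k−1, N−k) df; BH across the 14 genes; Tukey
HSD post hoc contrasts only for genes with q < 0.05. The Tukey
statistic uses the Tukey–Kramer pooled form
q = |x̄₁ − x̄₂| / √(MSW/2·(1/n₁ + 1/n₂)) with the Studentized range law
on (3, N−3). Degenerate inputs (zero within-group variance) return
(∞, 0) for unequal means and (NaN, NaN) for equal means, flagged in
the table rather than raised. Fold-changes: the primary column is
2^(Δ of log2 means); a `ratio_log2_means` column (x̄₂/x̄₁ of the log2
means themselves) is reported alongside because published per-gene
folds in this literature often follow the plain-ratio convention
(3.61 → 7.18 printed as 1.99-fold), and the two conventions diverge
wildly for low-expressed genes. No claim is made about which convention
any given published table used; both are computed.

## Classifier

Architecture 14 → [Linear → BatchNorm → ReLU → Dropout] ×
(64, 32, 16) → Linear → softmax, dropout 0.3/0.3/0.2, batchnorm ε =
1e-5 with running-statistic momentum 0.1. Training: cross-entropy (p
clamped at 1e-12 under the log) plus λ‖W‖² with λ = 1e-5 on weights
only (not biases or batchnorm parameters); Adam (α = 1e-3, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8) with bias correction; mini-batches of 32 with
per-epoch shuffling; remainder batches are kept unless of size 1
(batch statistics undefined — at most one sample per epoch is
deferred); validation accuracy evaluated once per epoch on the full
validation set drives a plateau scheduler (halve the rate after 15
non-improving epochs) and early stopping (30), with the
best-validation checkpoint restored. Weights use symmetric uniform
fan-based (Glorot) initialization under seed control; max 300 epochs.
Inference uses running batchnorm statistics and no dropout; gradients
are fully analytic and are verified against central finite differences.
Standardization uses per-gene training-set statistics only, with the
sample (n−1) standard deviation; at training-set sizes the n vs n−1
distinction is a 0.1% scale factor. Splitting is stratified 70/15/15
(476/102/102 at n = 680) via seeded stratified selection. Metrics:
accuracy, one-vs-rest precision/recall/F1, a row-normalized confusion
matrix, and trapezoidal one-vs-rest ROC AUC with thresholds at each
distinct predicted probability; a class absent from the test set gets
NaN recall/AUC and a flag. Mixed precision is pointless at this scale;
everything is float64.

## Attribution

Expected gradients: for an explained sample x, contributions
φ_j ≈ E_{b,α}[(x_j − b_j)·∂f/∂x_j |_{b+α(x−b)}] with b cycled evenly
through the background set (seeded shuffle) and α ~ U(0, 1);
path_samples defaults to 200, background/explained sets default to
100/100 seeded draws from the train/test splits. f is the class
probability of the inference network. Completeness (Σφ = f(x) − E_b f)
holds in expectation and within ~2% at path_samples ≥ 200 on toy
networks. On a network in its active (affine) region the estimator
equals the exhaustive-coalition Shapley value up to softmax curvature;
on kinked ReLU networks the two genuinely diverge and tests use a
looser proximity bound. Gene importance is the mean of |φ| over
explained samples for the carcinoma class (mean-of-absolutes, read
literally); interaction importance is the mean absolute product of hub
and target contributions, ranked with the rank-1/rank-2 percentage gap
reported. The hub's 13 panel partners (12 targets plus the other
receptor) are all ranked.

## PPI evidence

The filter reads the whitespace-delimited detailed-links dialect
(header with `protein1 protein2 ... experimental database
combined_score`, scores 0–1000) and a three-column alias table. Panel
symbols map to canonical protein identifiers; conflicting mappings are
an error, unmapped symbols are reported. Directed duplicate edges
collapse (score disagreements keep the maximum); malformed rows are
skipped and counted. The ">0" threshold is implemented as
experimental ≥ 1. Tests ship a small synthetic fixture in the same
dialect; the multi-gigabyte real files are never required.

## Pipeline

One global seed; per-module seeds derive as
`sha256(f"{seed}:{module}") mod 2^31`, so each stage can be re-run in
isolation and reproduce the full run. The consolidated report carries a
config hash and is validated against the checked-in
`report_schema.json`. The convergence section is computed, never
hand-entered: it checks whether the same hub pair tops the overall-ΔR²
ranking, the fold-change ranking, and the interaction-importance
ranking.

## Problem sizes in the test suite

Calibration under the global null uses 1000 replicate cohorts of 40
samples per stage; trajectory recovery uses 200 replicates at the full
158/170/352 sizes with Fisher-z 95% intervals; batch-correction
recovery uses 200 samples per batch; attribution pair-recovery uses 10
seeds at 80/80/120 with path_samples 100. These sizes keep the full
suite around two minutes while leaving Monte-Carlo error well inside
the asserted bands.

## Known limitations

The linear-hub generative model cannot express coupling that is not
mediated by the hub; planting an arbitrary 14×14 correlation matrix
would need a full Gaussian copula. The classifier has no
hyperparameter search and a fixed architecture. Attribution explains
class probabilities, not logits; explaining logits would change
absolute φ scales but not rankings in practice. The fold-ratio
convention ambiguity above means per-gene "fold" values should always
be read together with the stage means.
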