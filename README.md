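# ddrcoupling

Stage-stratified coexpression-coupling analysis of a 14-gene
DDR–collagen–MMP panel across the colorectal adenoma–carcinoma
sequence, with a synthetic-cohort generator that makes every stage of
the analysis testable without any data download.

## The problem

During colorectal tumorigenesis the extracellular matrix is remodelled
by a circuit of collagen-sensing receptor tyrosine kinases (DDR1,
DDR2), fibrillar collagen genes (COL1A1, COL1A2, COL3A1, COL5A1,
COL5A2, COL11A1, FN1) and matrix metalloproteinases (MMP1, MMP2, MMP7,
MMP9, MMP11). The interesting signal is not only *how much* each gene
changes between normal mucosa, adenoma and carcinoma, but how tightly
the receptors' expression becomes *coupled* to their targets — pairwise
coupling quantified per disease stage as R² = r², the squared Pearson
correlation

r_ij = Σ_k (x_ik − x̄_i)(x_jk − x̄_j) / √(Σ_k (x_ik − x̄_i)² Σ_k (x_jk − x̄_j)²)

computed within each stage and corrected for multiple testing with
Benjamini–Hochberg across the 91 panel pairs. The package is aimed at
computational biologists who want to apply (or stress-test) this
stage-stratified coupling methodology: trajectory deltas and folds with
kinetic classes ("de novo" activation from a near-zero baseline versus
"progressive" strengthening), hub summaries (mean R² of a DDR receptor
over its 12 targets), ANOVA + Tukey HSD differential expression,
empirical-Bayes batch correction of the location/scale form
Y = α + Xβ + γ + δε, a feed-forward stage classifier
(14 → 64 → 32 → 16 → 3 with batchnorm, dropout 0.3/0.3/0.2, Adam,
cross-entropy + L2), and gradient-based Shapley attribution with the
hub-interaction statistic

I(hub, j) = (1/N) Σ_k | φ_hub(k) · φ_j(k) |.

All randomness flows from explicit integer seeds; every module is
backed by an independent oracle in the test suite (brute-force
correlation sums, numeric integration of the Studentized range law,
exhaustive Shapley coalitions, `sva::ComBat` for the batch model).

## Worked example

```python
import pandas as pd
from ddrcoupling import (default_spec, generate_dataset,
                         stage_correlation_table, coupling_trajectory,
                         hub_coupling_summary, hub_targets)
from ddrcoupling.panel import STAGES

X, ann = generate_dataset(default_spec(seed=2, batch_effects=False))
records = pd.concat([stage_correlation_table(X, ann, s) for s in STAGES],
                    ignore_index=True)
traj = coupling_trajectory(records, ("DDR2", "COL11A1"))
print({k: round(v, 3) for k, v in traj.r_squared_by_stage.items()},
      traj.kinetic_class)
summary = hub_coupling_summary(records, "DDR2", hub_targets("DDR2"))
print({k: round(v, 3) for k, v in summary.mean_r2_by_stage.items()},
      round(summary.overall_fold, 2))
```

prints (seed 2):

```
{'normal': 0.016, 'adenoma': 0.226, 'carcinoma': 0.598} de_novo
{'normal': 0.134, 'adenoma': 0.213, 'carcinoma': 0.381} 2.83
```

The DDR2–COL11A1 pair rises from a near-zero baseline to R² ≈ 0.6 in
carcinoma (kinetic class "de novo"), and DDR2's mean coupling over its
12 targets strengthens ~2.6–2.8-fold — the generator's planted
conditions (0.007 → 0.235 → 0.549 for the pair; stage means 0.147 →
0.234 → 0.380 for the hub) recovered from one 680-sample draw.

The `examples/` directory has one short script per capability
(simulation, batch correction, coupling trajectories, differential
expression, classifier, attribution, PPI evidence filtering, full
pipeline). A thin CLI wraps the same functions:

```bash
ddrcoupling simulate --out-prefix cohort --seed 1
ddrcoupling run --out-dir results_run --seed 1
```

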