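"""Remove planted batch effects with the empirical-Bayes location/scale
model while preserving the disease-stage signal."""

import numpy as np

from ddrcoupling import combat_correct, default_spec, generate_dataset

spec = default_spec(seed=7)  # five pseudo-batches with gamma/delta effects
X, ann = generate_dataset(spec)

corrected, model = combat_correct(X, ann)

gene = "COL11A1"
for frame, label in ((X, "before"), (corrected, "after")):
    by_batch = [
        frame.loc[gene, ann.loc[ann["batch"] == b, "sample_id"]].mean()
        for b in sorted(ann["batch"].unique())
    ]
    print(f"{label:6s} per-batch {gene} means:", np.round(by_batch, 2))

stage_means = {
    s: corrected.loc[gene, ann.loc[ann["stage"] == s, "sample_id"]].mean()
    for s in ("normal", "adenoma", "carcinoma")
}
print("stage means after correction:", {k: round(v, 2) for k, v in stage_means.items()})
# Batch means converge after correction while the planted stage
# trajectory (3.61 -> 4.84 -> 7.18) survives, because the stage design
# is supplied as the biological covariate.
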