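"""Gradient-based Shapley attribution over a trained classifier:
per-gene importance and hub-target interaction importance."""

from ddrcoupling import (
    ClassifierConfig,
    Standardizer,
    gene_importance,
    generate_dataset,
    gradient_shap,
    interaction_importance,
    stratified_split,
    train_classifier,
    unique_pair_spec,
)
from ddrcoupling.panel import STAGES

# conditions in which DDR2-COL11A1 is the uniquely strengthening pair
X, ann = generate_dataset(unique_pair_spec(seed=2))
train_ids, val_ids, test_ids = stratified_split(ann, seed=2)
std = Standardizer.fit(X[train_ids])
labels = ann.set_index("sample_id")["stage"].map({s: i for i, s in enumerate(STAGES)})

model = train_classifier(
    ClassifierConfig(seed=2),
    std.transform(X[train_ids]).T.to_numpy(), labels[train_ids].to_numpy(),
    std.transform(X[val_ids]).T.to_numpy(), labels[val_ids].to_numpy(),
)

result = gradient_shap(
    model,
    std.transform(X[train_ids]).T.to_numpy()[:100],   # background references
    std.transform(X[test_ids]).T.to_numpy(),          # explained samples
    path_samples=200,
    seed=2,
    genes=tuple(X.index),
)

imp = gene_importance(result, "carcinoma")
print("top genes by mean |phi| (carcinoma class):")
print(imp.head(5).round(4).to_string(index=False))

inter = interaction_importance(result, "DDR2", tuple(g for g in X.index if g != "DDR2"))
print("\ntop DDR2 interactions by mean |phi_hub * phi_target|:")
print(inter.head(3).round(5).to_string(index=False))
print(f"rank-1 vs rank-2 gap: {inter.attrs['top_gap_pct']:.1f}%")
# COL11A1 carries the dominant attribution and DDR2-COL11A1 tops the
# interaction ranking -- the attribution route recovers the planted
# coupled pair independently of the correlation analysis.
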