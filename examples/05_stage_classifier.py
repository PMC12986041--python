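"""Train the feed-forward stage classifier on a batch-corrected cohort
and evaluate it on the held-out test split."""

from ddrcoupling import (
    ClassifierConfig,
    Standardizer,
    combat_correct,
    default_spec,
    evaluate,
    generate_dataset,
    stratified_split,
    train_classifier,
)
from ddrcoupling.panel import STAGES

X, ann = generate_dataset(default_spec(seed=11))
X, _ = combat_correct(X, ann)

train_ids, val_ids, test_ids = stratified_split(ann, seed=11)
print(f"split: train {len(train_ids)} / val {len(val_ids)} / test {len(test_ids)}")

std = Standardizer.fit(X[train_ids])  # training statistics only
labels = ann.set_index("sample_id")["stage"].map({s: i for i, s in enumerate(STAGES)})

model = train_classifier(
    ClassifierConfig(seed=11),
    std.transform(X[train_ids]).T.to_numpy(), labels[train_ids].to_numpy(),
    std.transform(X[val_ids]).T.to_numpy(), labels[val_ids].to_numpy(),
)
metrics = evaluate(model, std.transform(X[test_ids]).T.to_numpy(),
                   labels[test_ids].to_numpy())

print(f"trained {len(model.history['train_loss'])} epochs; "
      f"best val accuracy {model.best_val_accuracy:.4f}")
print(f"test accuracy: {metrics.accuracy:.4f}")
print("one-vs-rest AUC:", {k: round(v, 3) for k, v in metrics.auc.items()})
print("row-normalized confusion matrix:")
print(metrics.confusion.round(3).to_string())
# With the planted stage structure the held-out accuracy lands well
# above 0.9 and every AUC near 1; the confusion matrix shows the
# normal/adenoma boundary carries what little error remains.
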