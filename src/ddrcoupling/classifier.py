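"""Feed-forward disease-stage classifier on the 14-gene panel.

Architecture: input(14) -> [Linear -> BatchNorm -> ReLU -> Dropout] x 3
with hidden widths (64, 32, 16) and dropout rates (0.3, 0.3, 0.2),
followed by a Linear output to 3 class logits and softmax.  Training
minimises cross-entropy plus an L2 penalty on the weights (not biases
or batchnorm parameters) with the Adam optimizer, mini-batches of 32
with per-epoch shuffling, a plateau scheduler halving the learning rate
after 15 non-improving validation epochs, early stopping after 30, and
restoration of the best-validation checkpoint.

Everything is implemented with numpy and analytic backpropagation so
the gradients used for training are the same ones the attribution
module integrates along background paths.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _confusion_matrix
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import train_test_split

from .panel import STAGES

__all__ = [
    "ClassifierConfig",
    "FeedForwardClassifier",
    "ClassificationMetrics",
    "stratified_split",
    "train_classifier",
    "evaluate",
]

_PROB_CLAMP = 1e-12  # floor under log() in the cross-entropy


@dataclass
class ClassifierConfig:
    input_dim: int = 14
    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    dropout_rates: tuple[float, ...] = (0.3, 0.3, 0.2)
    n_classes: int = 3
    batchnorm_epsilon: float = 1e-5
    batchnorm_momentum: float = 0.1
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    l2_lambda: float = 1e-5
    batch_size: int = 32
    lr_factor: float = 0.5
    lr_patience: int = 15
    early_stop_patience: int = 30
    max_epochs: int = 300
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if len(self.hidden_sizes) != len(self.dropout_rates):
            raise ValueError("one dropout rate per hidden layer required")
        for p in self.dropout_rates:
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


def stratified_split(
    annotation: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, exhaustive train/validation/test partition preserving
    stage proportions (within one sample per stage).  Deterministic
    given the seed."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = annotation["sample_id"].tolist()
    stages = annotation["stage"].tolist()
    n = len(ids)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    if n_train >= n:
        return ids, [], []
    train_ids, rest_ids, _, rest_stages = train_test_split(
        ids, stages, train_size=n_train, stratify=stages, random_state=seed
    )
    if n_val == 0:
        return train_ids, [], rest_ids
    if n_val >= len(rest_ids):
        return train_ids, rest_ids, []
    val_ids, test_ids = train_test_split(
        rest_ids, train_size=n_val, stratify=rest_stages, random_state=seed
    )
    return train_ids, val_ids, test_ids


# ---------------------------------------------------------------------------
# the network


class FeedForwardClassifier:
    """Numpy MLP with analytic backprop (see module docstring)."""

    def __init__(self, config: ClassifierConfig):
        config.validate()
        self.config = config
        self.classes: tuple[str, ...] = STAGES
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_sizes, config.n_classes]
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.params[f"W{i}"] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
            if i < len(config.hidden_sizes):
                self.params[f"bn_gamma{i}"] = np.ones(fan_out)
                self.params[f"bn_beta{i}"] = np.zeros(fan_out)
                self.running[f"mean{i}"] = np.zeros(fan_out)
                self.running[f"var{i}"] = np.ones(fan_out)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        self.history: dict[str, list[float]] = {
            "train_loss": [],
            "val_accuracy": [],
            "learning_rate": [],
        }

    # -- forward -----------------------------------------------------------

    def forward(
        self, X: np.ndarray, train: bool = False, update_running: bool = True
    ) -> tuple[np.ndarray, dict]:
        """Class probabilities (n_samples x n_classes) and the cache
        needed for backprop.  Train mode uses mini-batch statistics and
        dropout; eval mode uses running statistics and no dropout."""
        cfg = self.config
        if X.shape[1] != cfg.input_dim:
            raise ValueError(f"expected {cfg.input_dim} input features, got {X.shape[1]}")
        if train and X.shape[0] < 2:
            raise ValueError("batch statistics undefined for a train batch of size 1")
        cache: dict = {"inputs": [], "bn": [], "relu": [], "drop": [], "train": train}
        h = X
        n_hidden = len(cfg.hidden_sizes)
        for i in range(n_hidden):
            cache["inputs"].append(h)
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if train:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                if update_running:
                    m = cfg.batchnorm_momentum
                    n_b = z.shape[0]
                    unbiased = var * n_b / max(n_b - 1, 1)
                    self.running[f"mean{i}"] = (1 - m) * self.running[f"mean{i}"] + m * mu
                    self.running[f"var{i}"] = (1 - m) * self.running[f"var{i}"] + m * unbiased
            else:
                mu = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            inv_sd = 1.0 / np.sqrt(var + cfg.batchnorm_epsilon)
            xhat = (z - mu) * inv_sd
            a = self.params[f"bn_gamma{i}"] * xhat + self.params[f"bn_beta{i}"]
            cache["bn"].append((xhat, inv_sd))
            relu_mask = a > 0
            h = a * relu_mask
            cache["relu"].append(relu_mask)
            if train and cfg.dropout_rates[i] > 0:
                keep = 1.0 - cfg.dropout_rates[i]
                mask = (self._dropout_rng.random(h.shape) < keep) / keep
                h = h * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
        cache["inputs"].append(h)
        logits = h @ self.params[f"W{n_hidden}"] + self.params[f"b{n_hidden}"]
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(np.asarray(X, float), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- backward ----------------------------------------------------------

    def loss_and_grads(
        self, X: np.ndarray, y_onehot: np.ndarray, train: bool = True
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy + L2(weights) loss and analytic gradients."""
        cfg = self.config
        probs, cache = self.forward(X, train=train)
        n = X.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(np.maximum(probs, _PROB_CLAMP)), axis=1))
        n_hidden = len(cfg.hidden_sizes)
        l2 = sum(np.sum(self.params[f"W{i}"] ** 2) for i in range(n_hidden + 1))
        loss += cfg.l2_lambda * l2

        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot) / n
        h_last = cache["inputs"][n_hidden]
        grads[f"W{n_hidden}"] = h_last.T @ dlogits + 2 * cfg.l2_lambda * self.params[f"W{n_hidden}"]
        grads[f"b{n_hidden}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params[f"W{n_hidden}"].T
        for i in reversed(range(n_hidden)):
            if cache["drop"][i] is not None:
                dh = dh * cache["drop"][i]
            da = dh * cache["relu"][i]
            xhat, inv_sd = cache["bn"][i]
            grads[f"bn_gamma{i}"] = np.sum(da * xhat, axis=0)
            grads[f"bn_beta{i}"] = da.sum(axis=0)
            dxhat = da * self.params[f"bn_gamma{i}"]
            if cache["train"]:
                m = X.shape[0]
                dz = inv_sd * (
                    dxhat
                    - dxhat.mean(axis=0)
                    - xhat * np.mean(dxhat * xhat, axis=0)
                )
            else:
                dz = dxhat * inv_sd
            h_in = cache["inputs"][i]
            grads[f"W{i}"] = h_in.T @ dz + 2 * cfg.l2_lambda * self.params[f"W{i}"]
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return float(loss), grads

    def input_gradients(self, X: np.ndarray, class_index: int) -> np.ndarray:
        """d p_class / d x per sample, in eval mode (running batchnorm
        statistics, no dropout) -- the deterministic inference network."""
        cfg = self.config
        X = np.asarray(X, float)
        probs, cache = self.forward(X, train=False)
        n_hidden = len(cfg.hidden_sizes)
        # d p_c / d logits = p_c * (e_c - p)
        pc = probs[:, class_index][:, None]
        dlogits = pc * (-probs)
        dlogits[:, class_index] += probs[:, class_index]
        dh = dlogits @ self.params[f"W{n_hidden}"].T
        for i in reversed(range(n_hidden)):
            da = dh * cache["relu"][i]
            dxhat = da * self.params[f"bn_gamma{i}"]
            _, inv_sd = cache["bn"][i]
            dz = dxhat * inv_sd
            dh = dz @ self.params[f"W{i}"].T
        return dh

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.running = {k: v.copy() for k, v in state["running"].items()}


# ---------------------------------------------------------------------------
# training


class AdamOptimizer:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params: dict[str, np.ndarray], config: ClassifierConfig):
        self.lr = config.learning_rate
        self.beta1 = config.adam_beta1
        self.beta2 = config.adam_beta2
        self.eps = config.adam_epsilon
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _onehot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train_classifier(
    config: ClassifierConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> FeedForwardClassifier:
    """Train with mini-batches, plateau LR scheduling, early stopping
    and best-validation checkpoint restoration.

    ``X_*`` are standardized sample x gene arrays; ``y_*`` integer class
    labels indexed against the canonical stage order."""
    model = FeedForwardClassifier(config)
    opt = AdamOptimizer(model.params, config)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[1]
    )
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_oh = _onehot(np.asarray(y_train), config.n_classes)

    best_acc = -np.inf
    best_state = model.state_dict()
    since_improve = 0
    since_lr_drop = 0
    n = len(X_train)
    for _epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) == 1:
                continue  # batch statistics undefined; remainder of 1 skipped
            loss, grads = model.loss_and_grads(X_train[idx], y_oh[idx], train=True)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {_epoch}")
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_acc = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
        model.history["train_loss"].append(epoch_loss / max(n_batches, 1))
        model.history["val_accuracy"].append(val_acc)
        model.history["learning_rate"].append(opt.lr)

        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            since_improve = 0
            since_lr_drop = 0
        else:
            since_improve += 1
            since_lr_drop += 1
        if since_lr_drop >= config.lr_patience:
            opt.lr *= config.lr_factor
            since_lr_drop = 0
        if since_improve >= config.early_stop_patience:
            break

    model.load_state_dict(best_state)
    model.best_val_accuracy = best_acc
    return model


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: pd.DataFrame  # row-normalized, rows = true class
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)
    absent_classes: list[str] = field(default_factory=list)


def evaluate(
    model: FeedForwardClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    class_names: tuple[str, ...] = STAGES,
) -> ClassificationMetrics:
    """Accuracy, one-vs-rest precision/recall/F1, row-normalized
    confusion matrix and trapezoidal ROC AUC per class.

    ROC thresholds sweep each distinct predicted probability of the
    class under consideration.  A class absent from the test set gets
    NaN recall/AUC and is flagged."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    y_test = np.asarray(y_test)
    probs = model.predict_proba(np.asarray(X_test, float))
    pred = probs.argmax(axis=1)
    labels = list(range(len(class_names)))
    accuracy = float(np.mean(pred == y_test))

    precision, recall, f1 = {}, {}, {}
    absent = []
    for c, name in enumerate(class_names):
        tp = int(np.sum((pred == c) & (y_test == c)))
        fp = int(np.sum((pred == c) & (y_test != c)))
        fn = int(np.sum((pred != c) & (y_test == c)))
        precision[name] = tp / (tp + fp) if tp + fp else float("nan")
        if tp + fn == 0:
            absent.append(name)
            recall[name] = float("nan")
        else:
            recall[name] = tp / (tp + fn)
        pr, rc = precision[name], recall[name]
        f1[name] = (
            2 * pr * rc / (pr + rc)
            if np.isfinite(pr) and np.isfinite(rc) and (pr + rc) > 0
            else float("nan")
        )

    cm = _confusion_matrix(y_test, pred, labels=labels).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_norm = np.where(row_sums > 0, cm / row_sums, np.nan)
    confusion = pd.DataFrame(cm_norm, index=class_names, columns=class_names)

    roc_curves, aucs = {}, {}
    for c, name in enumerate(class_names):
        if name in absent or bool(np.all(y_test == c)):
            # one-vs-rest discrimination undefined without both groups
            aucs[name] = float("nan")
            continue
        fpr, tpr, _ = _roc_curve(y_test == c, probs[:, c])
        roc_curves[name] = (fpr, tpr)
        aucs[name] = float(_trapezoid_auc(fpr, tpr))

    return ClassificationMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=confusion,
        roc_curves=roc_curves,
        auc=aucs,
        absent_classes=absent,
    )
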