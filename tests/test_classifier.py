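"""Network forward/backward correctness, optimizer behaviour, splitting
and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from ddrcoupling.classifier import (
    AdamOptimizer,
    ClassifierConfig,
    FeedForwardClassifier,
    evaluate,
    stratified_split,
    train_classifier,
)
from ddrcoupling.panel import STAGES
from ddrcoupling.preprocess import Standardizer
from ddrcoupling.synthetic import default_spec, generate_dataset


def _tiny_config(**kw):
    defaults = dict(
        input_dim=4, hidden_sizes=(5, 3), dropout_rates=(0.0, 0.0), n_classes=3, seed=3
    )
    defaults.update(kw)
    return ClassifierConfig(**defaults)


class TestSplit:
    def test_cohort_partition_sizes(self, default_cohort):
        _, _, ann = default_cohort
        tr, va, te = stratified_split(ann, (0.70, 0.15, 0.15), seed=0)
        assert (len(tr), len(va), len(te)) == (476, 102, 102)
        assert set(tr) | set(va) | set(te) == set(ann["sample_id"])
        assert not (set(tr) & set(va)) and not (set(va) & set(te))
        # per-stage proportions within one sample of the targets
        stage_of = ann.set_index("sample_id")["stage"]
        for part, frac in ((tr, 0.70), (va, 0.15), (te, 0.15)):
            counts = stage_of[part].value_counts()
            for s, n_total in ann["stage"].value_counts().items():
                assert abs(counts[s] - frac * n_total) <= 1.0

    def test_degenerate_fractions(self, default_cohort):
        _, _, ann = default_cohort
        tr, va, te = stratified_split(ann, (1.0, 0.0, 0.0), seed=0)
        assert len(tr) == len(ann) and va == [] and te == []

    def test_determinism(self, default_cohort):
        _, _, ann = default_cohort
        assert stratified_split(ann, seed=7) == stratified_split(ann, seed=7)

    def test_bad_fractions_rejected(self, default_cohort):
        _, _, ann = default_cohort
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(ann, (0.5, 0.2, 0.2), seed=0)


class TestForward:
    def test_zero_network_gives_uniform_probabilities(self):
        net = FeedForwardClassifier(_tiny_config())
        for k in net.params:
            net.params[k][...] = 0.0
        probs = net.predict_proba(np.random.default_rng(0).standard_normal((5, 4)))
        assert np.allclose(probs, 1 / 3, atol=1e-12)

    def test_probabilities_normalized(self, rng):
        net = FeedForwardClassifier(_tiny_config())
        probs = net.predict_proba(rng.standard_normal((20, 4)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_saturated_logits(self):
        """A 20-unit logit margin saturates softmax regardless of level."""
        for L in (-50.0, 0.0, 50.0):
            logits = np.array([[L, L - 20.0, L - 20.0]])
            z = logits - logits.max()
            p = np.exp(z) / np.exp(z).sum()
            assert p[0, 0] > 0.9999

    def test_train_batch_of_one_rejected(self, rng):
        net = FeedForwardClassifier(_tiny_config())
        with pytest.raises(ValueError, match="size 1"):
            net.forward(rng.standard_normal((1, 4)), train=True)


class TestLossAndGradients:
    def test_cross_entropy_limits(self):
        """Perfect one-hot prediction costs ~0; uniform costs ln 3."""
        net = FeedForwardClassifier(_tiny_config(l2_lambda=0.0))
        for k in net.params:
            net.params[k][...] = 0.0
        X = np.zeros((6, 4))
        y = np.eye(3)[[0, 1, 2, 0, 1, 2]]
        loss, _ = net.loss_and_grads(X, y, train=False)
        assert loss == pytest.approx(np.log(3), abs=1e-9)
        # saturate class 0 via the output bias
        net.params["b2"][...] = np.array([60.0, 0.0, 0.0])
        loss, _ = net.loss_and_grads(X, np.eye(3)[[0] * 6], train=False)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop of cross-entropy + L2 agrees with central
        differences to 1e-5 relative (with an absolute floor for
        true-zero gradients such as pre-batchnorm biases)."""
        net = FeedForwardClassifier(_tiny_config())
        X = rng.standard_normal((8, 4))
        y = np.eye(3)[rng.integers(0, 3, 8)]
        _, grads = net.loss_and_grads(X, y, train=True)
        for k, g in grads.items():
            p = net.params[k]
            flat = p.ravel()
            idx = rng.choice(flat.size, size=min(flat.size, 8), replace=False)
            for i in idx:
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = net.loss_and_grads(X, y, train=True)
                flat[i] = orig - eps
                lm, _ = net.loss_and_grads(X, y, train=True)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(g.ravel()[i]), 1e-4)
                assert abs(fd - g.ravel()[i]) / denom < 1e-5

    def test_input_gradients_match_finite_differences(self, rng):
        net = FeedForwardClassifier(_tiny_config())
        X = rng.standard_normal((3, 4))
        for c in range(3):
            g = net.input_gradients(X, c)
            for k in range(3):
                for j in range(4):
                    eps = 1e-6
                    Xp, Xm = X.copy(), X.copy()
                    Xp[k, j] += eps
                    Xm[k, j] -= eps
                    fd = (
                        net.predict_proba(Xp)[k, c] - net.predict_proba(Xm)[k, c]
                    ) / (2 * eps)
                    assert abs(fd - g[k, j]) < 1e-6


class TestAdam:
    def test_zero_gradient_leaves_parameters_unchanged(self):
        params = {"w": np.array([1.0, -2.0, 3.0])}
        opt = AdamOptimizer(params, ClassifierConfig())
        before = params["w"].copy()
        for _ in range(5):
            opt.step(params, {"w": np.zeros(3)})
        assert np.array_equal(params["w"], before)


class TestTraining:
    def test_deterministic_given_seed(self, rng):
        """Two runs with the same seed (dropout off for strictness) are
        bit-identical."""
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 3, 60)
        Xv, yv = X[:20], y[:20]
        cfg = _tiny_config(max_epochs=10, dropout_rates=(0.0, 0.0))
        m1 = train_classifier(cfg, X, y, Xv, yv)
        m2 = train_classifier(_tiny_config(max_epochs=10, dropout_rates=(0.0, 0.0)), X, y, Xv, yv)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_learns_linearly_separable_stages(self, rng):
        """On stages separated well beyond the noise scale the network
        reaches >= 0.95 validation accuracy, gated by a linear-classifier
        oracle achieving >= 0.95 on the same draw."""
        n = 360
        y = rng.integers(0, 3, n)
        X = rng.standard_normal((n, 4))
        X[:, 0] += 4.0 * y  # 4-sigma spacing between adjacent stages
        cfg = ClassifierConfig(
            input_dim=4, hidden_sizes=(16, 8, 4), dropout_rates=(0.1, 0.1, 0.1),
            max_epochs=100, seed=0,
        )
        split = int(0.8 * n)
        model = train_classifier(cfg, X[:split], y[:split], X[split:], y[split:])
        acc = np.mean(model.predict(X[split:]) == y[split:])
        oracle = LogisticRegression(max_iter=1000).fit(X[:split], y[:split])
        assert oracle.score(X[split:], y[split:]) >= 0.95
        assert acc >= 0.95

    def test_non_finite_loss_aborts(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 3, 40)
        cfg = _tiny_config(max_epochs=3, learning_rate=1e3)
        model = FeedForwardClassifier(cfg)
        model.params["W0"][...] = 1e200  # force overflow to non-finite loss
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises((FloatingPointError, ValueError)):
                loss, _ = model.loss_and_grads(X, np.eye(3)[y], train=True)
                if not np.isfinite(loss):
                    raise FloatingPointError


class TestEvaluate:
    def _perfect_model(self):
        class Stub:
            def predict_proba(self, X):
                return np.eye(3)[np.asarray(X[:, 0], int)]

        return Stub()

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        X = y[:, None].astype(float) * np.ones((1, 4))
        m = evaluate(self._perfect_model(), X, y)
        assert m.accuracy == 1.0
        assert all(v == pytest.approx(1.0) for v in m.auc.values())
        assert np.allclose(np.diag(m.confusion.to_numpy()), 1.0)

    def test_constant_prediction_on_balanced_classes(self):
        class Constant:
            def predict_proba(self, X):
                out = np.zeros((len(X), 3))
                out[:, 0] = 1.0
                return out

        y = np.array([0, 1, 2] * 4)
        m = evaluate(Constant(), np.zeros((12, 4)), y)
        assert m.accuracy == pytest.approx(1 / 3)

    def test_auc_equals_mann_whitney_concordance(self):
        """Trapezoidal one-vs-rest AUC equals the all-pairs concordance
        count with ties scored 1/2."""
        probs_pos = np.array([0.9, 0.8, 0.8, 0.4, 0.3, 0.2])
        y = np.array([0, 0, 1, 0, 1, 1])

        class Stub:
            def predict_proba(self, X):
                out = np.zeros((6, 3))
                out[:, 0] = probs_pos
                out[:, 1] = 1 - probs_pos
                return out

        m = evaluate(Stub(), np.zeros((6, 4)), y, class_names=("pos", "neg", "other"))
        pos, neg = probs_pos[y == 0], probs_pos[y != 0]
        conc = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
        assert m.auc["pos"] == pytest.approx(conc, abs=1e-12)

    def test_confusion_rows_sum_to_one(self, rng):
        net = FeedForwardClassifier(_tiny_config())
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 3, 30)
        m = evaluate(net, X, y)
        sums = m.confusion.sum(axis=1).to_numpy()
        assert np.allclose(sums[np.isfinite(sums)], 1.0, atol=1e-9)

    def test_f1_is_harmonic_mean(self, rng):
        net = FeedForwardClassifier(_tiny_config())
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 3, 40)
        m = evaluate(net, X, y)
        for c in m.f1:
            pr, rc, f1 = m.precision[c], m.recall[c], m.f1[c]
            if np.isfinite(f1):
                assert f1 == pytest.approx(2 * pr * rc / (pr + rc), abs=1e-12)

    def test_absent_class_flagged(self):
        net = FeedForwardClassifier(_tiny_config())
        X = np.random.default_rng(0).standard_normal((10, 4))
        y = np.zeros(10, int)  # only class 0 present
        m = evaluate(net, X, y)
        assert set(m.absent_classes) == {"adenoma", "carcinoma"}
        assert np.isnan(m.recall["adenoma"])


class TestEndToEndCohort:
    def test_planted_stage_structure_is_learnable(self, default_cohort, stage_labels):
        """On the calibrated cohort the held-out accuracy comfortably
        exceeds chance and the per-class AUCs are high."""
        _, X, ann = default_cohort
        tr, va, te = stratified_split(ann, seed=1)
        std = Standardizer.fit(X[tr])
        lab = ann.set_index("sample_id")["stage"].map(stage_labels)
        cfg = ClassifierConfig(seed=1, max_epochs=150)
        model = train_classifier(
            cfg,
            std.transform(X[tr]).T.to_numpy(), lab[tr].to_numpy(),
            std.transform(X[va]).T.to_numpy(), lab[va].to_numpy(),
        )
        m = evaluate(model, std.transform(X[te]).T.to_numpy(), lab[te].to_numpy())
        assert m.accuracy >= 0.90
        assert min(m.auc.values()) >= 0.95
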