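"""Classification head, loss closed forms, prediction contract and k-fold CV."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from screformer._nn.functional import softmax
from screformer.finetune import (
    ClassifierHead,
    CrossValidationResult,
    ReformerCellClassifier,
    classify,
    cls_loss,
    cross_validate,
)


class TestClassify:
    def test_uniform_probabilities_when_logits_equal(self, rng):
        head = ClassifierHead(6, 4, d_conv=5, hidden=(7, 7), dropout=0.0,
                              rng=np.random.default_rng(0))
        for layer in head._layers.values():
            layer.params["W"][...] = 0
            layer.params["b"][...] = 0
        probs = classify(rng.standard_normal((10, 6)), head)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_softmax_shift_invariance(self, rng):
        head = ClassifierHead(6, 3, d_conv=4, hidden=(5, 5), dropout=0.0,
                              rng=np.random.default_rng(1))
        feats = rng.standard_normal((8, 6))
        base = classify(feats, head)
        head.out.params["b"][...] += 3.7  # constant shift of all logits
        np.testing.assert_allclose(classify(feats, head), base, atol=1e-9)

    def test_matches_layer_by_layer_oracle(self, rng):
        head = ClassifierHead(5, 3, d_conv=4, hidden=(6, 6), dropout=0.0,
                              rng=np.random.default_rng(2))
        feats = rng.standard_normal((7, 5))
        a = np.maximum(feats @ head.conv.params["W"] + head.conv.params["b"], 0)
        pooled = np.concatenate([a.mean(axis=0), a.max(axis=0)])
        h1 = np.maximum(pooled @ head.fc1.params["W"] + head.fc1.params["b"], 0)
        h2 = np.maximum(h1 @ head.fc2.params["W"] + head.fc2.params["b"], 0)
        logits = h2 @ head.out.params["W"] + head.out.params["b"]
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        np.testing.assert_allclose(classify(feats, head), expect, atol=1e-6)


class TestClsLoss:
    def test_perfect_prediction_zero(self):
        probs = np.eye(3)[[0, 2, 1]]
        assert cls_loss(probs, [0, 2, 1]) == 0.0

    def test_uniform_nine_class_closed_form(self):
        assert cls_loss(np.full((1, 9), 1 / 9), [4]) == pytest.approx(np.log(9), abs=1e-12)

    def test_uniform_batch_m_ln_c(self, rng):
        m, C = 17, 5
        z = rng.integers(0, C, m)
        assert cls_loss(np.full((m, C), 1 / C), z) == pytest.approx(m * np.log(C), abs=1e-9)

    def test_four_cell_hand_sum(self):
        probs = np.array([
            [0.7, 0.2, 0.1], [0.2, 0.5, 0.3], [0.05, 0.05, 0.9], [0.4, 0.4, 0.2],
        ])
        z = [0, 1, 2, 0]
        expect = -(np.log(0.7) + np.log(0.5) + np.log(0.9) + np.log(0.4))
        assert cls_loss(probs, z) == pytest.approx(expect, abs=1e-12)

    def test_zero_probability_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = cls_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(loss)


ARCH = dict(d_model=8, n_layers=1, n_heads=2, n_buckets=2, n_hash_rounds=1,
            n_bins=7, d_conv=8, hidden=(8, 8), dropout=0.0, batch_size=32,
            grad_acc=1)


class TestClassifier:
    def test_zero_lr_constant_validation_accuracy(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = small_dataset.labels.level1
        clf = ReformerCellClassifier(**ARCH, lr=0.0, max_epochs=3, patience=5, seed=0)
        clf.fit(X[:120], y[:120])
        assert clf.history_["val_accuracy"].nunique() == 1

    def test_seed_fixed_double_run_identical(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = small_dataset.labels.level1
        runs = [
            ReformerCellClassifier(**ARCH, lr=1e-3, max_epochs=2, patience=5, seed=9)
            .fit(X[:120], y[:120]).history_
            for _ in range(2)
        ]
        assert runs[0].equals(runs[1])

    def test_val_class_absent_from_train_rejected(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = np.array(small_dataset.labels.level1)
        train_mask = y != "type0"
        clf = ReformerCellClassifier(**ARCH, lr=1e-3, max_epochs=1, seed=0)
        with pytest.raises(ValueError, match="absent"):
            clf.fit(X[train_mask], y[train_mask], X_val=X, y_val=y)

    def test_predict_tie_break_lowest_class_index(self):
        # argmax over equal logits must pick the first class
        probs = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0]])
        assert probs[0].argmax() == 1
        assert probs[1].argmax() == 0  # documented tie rule

    def test_batched_equals_one_at_a_time(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = small_dataset.labels.level1
        clf = ReformerCellClassifier(**ARCH, lr=1e-3, max_epochs=1, patience=5, seed=4)
        clf.fit(X[:100], y[:100])
        batch = clf.predict_proba(X[100:116])
        singles = np.vstack([clf.predict_proba(X[i : i + 1]) for i in range(100, 116)])
        np.testing.assert_allclose(batch, singles, atol=1e-10)

    def test_sequence_length_mismatch_rejected(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = small_dataset.labels.level1
        clf = ReformerCellClassifier(**ARCH, lr=1e-3, max_epochs=1, seed=0)
        clf.fit(X[:80], y[:80])
        with pytest.raises(ValueError, match="length mismatch|expected"):
            clf.predict(X[:, :-1])

    def test_early_stopping_keeps_best_checkpoint(self, small_tokens, small_dataset):
        _, X = small_tokens
        y = small_dataset.labels.level1
        clf = ReformerCellClassifier(**ARCH, lr=3e-3, max_epochs=4, patience=4, seed=2)
        clf.fit(X[:150], y[:150])
        assert clf.best_val_accuracy_ == clf.history_["val_accuracy"].max()

    def test_sklearn_get_set_params(self):
        clf = ReformerCellClassifier()
        params = clf.get_params()
        assert params["seed"] == 2022 and params["max_epochs"] == 3
        clf.set_params(max_epochs=5)
        assert clf.max_epochs == 5


class _ConstantClassifier(ClassifierMixin, BaseEstimator):
    """Always predicts the first class it saw; oracle for fold prevalence."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        out = np.zeros((len(X), len(self.classes_)))
        out[:, 0] = 1.0
        return out

    def predict(self, X):
        return np.repeat(self.classes_[0], len(X))


class TestCrossValidate:
    def test_two_folds_on_ten_cells(self, rng):
        X = rng.random((10, 3))
        y = np.array(["a", "b"] * 5)
        res = cross_validate(_ConstantClassifier(), X, y, k=2, seed=0)
        sizes = sorted(len(f) for f in res.fold_test_indices)
        assert sizes == [5, 5]
        all_tested = np.sort(np.concatenate(res.fold_test_indices))
        np.testing.assert_array_equal(all_tested, np.arange(10))

    def test_constant_model_accuracy_equals_prevalence(self, rng):
        X = rng.random((40, 2))
        y = np.array(["a"] * 25 + ["b"] * 15)
        res = cross_validate(_ConstantClassifier(), X, y, k=4, seed=3)
        for rep, idx in zip(res.reports, res.fold_test_indices):
            prevalence = np.mean(y[idx] == "a")
            assert rep.accuracy == pytest.approx(prevalence)
        summary = res.summary()
        accs = res.accuracy
        assert summary.loc[summary.metric == "accuracy", "mean"].item() == pytest.approx(accs.mean())
        assert summary.loc[summary.metric == "accuracy", "sd"].item() == pytest.approx(accs.std(ddof=1))

    def test_folds_deterministic(self, rng):
        X = rng.random((30, 2))
        y = np.array(["a", "b", "c"] * 10)
        a = cross_validate(_ConstantClassifier(), X, y, k=3, seed=11)
        b = cross_validate(_ConstantClassifier(), X, y, k=3, seed=11)
        for fa, fb in zip(a.fold_test_indices, b.fold_test_indices):
            np.testing.assert_array_equal(fa, fb)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(_ConstantClassifier(), rng.random((3, 2)), ["a", "b", "a"], k=5)

    def test_rare_class_rejected(self, rng):
        X = rng.random((10, 2))
        y = ["a"] * 9 + ["b"]
        with pytest.raises(ValueError, match="at least k"):
            cross_validate(_ConstantClassifier(), X, y, k=3)
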