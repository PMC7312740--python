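"""Two-tier stacking: splits, out-of-fold integrity, averaging, and
end-to-end classifier behaviour on synthetic feature sets."""
import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from nodulebci.errors import DataError, ValidationError
from nodulebci.evaluation import roc_auc
from nodulebci.stacking import (average_test_predictions, build_level2_matrix,
                                default_base_specs,
                                fit_stacking, load_model, predict, save_model,
                                split_train_test)


class _Memorizer:
    """Probe learner: scores 1 for any sample row it saw during fit.

    Used to verify out-of-fold integrity — its out-of-fold column must be
    all zeros because no held-out sample was in its training part.
    """

    def __init__(self):
        self.seen = set()

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self

    def fit(self, X, y):
        self.seen = {row.tobytes() for row in np.asarray(X)}
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.array([1.0 if row.tobytes() in self.seen else 0.0
                      for row in np.asarray(X)])
        return np.column_stack([1 - p, p])


class _ConstantScorer:
    """Deterministic stub scoring a fixed value per fit call."""

    def __init__(self, values):
        self.values = values

    def get_params(self, deep=True):
        return {"values": self.values}

    def set_params(self, **kw):
        return self

    def fit(self, X, y):
        self.score = self.values[0]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.score)
        return np.column_stack([1 - p, p])


def gaussian_blobs(n=200, d=8, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, d))
    X[y == 1, 0] += sep
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestSplit:
    def test_stratified_1to1(self):
        X = np.arange(200).reshape(100, 2).astype(float)
        y = np.array([1] * 20 + [0] * 80)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=0)
        assert len(y_tr) == len(y_te) == 50
        assert y_tr.sum() == y_te.sum() == 10

    def test_reproducible(self):
        X, y = gaussian_blobs(60)
        a = split_train_test(X, y, seed=5)
        b = split_train_test(X, y, seed=5)
        assert np.array_equal(a[0], b[0])

    def test_odd_n_sizes(self):
        X = np.zeros((11, 2))
        y = np.array([0, 1] * 5 + [0])
        X_tr, X_te, _, _ = split_train_test(X, y, seed=0)
        assert sorted([len(X_tr), len(X_te)]) == [5, 6]

    def test_single_class_refused(self):
        with pytest.raises(DataError):
            split_train_test(np.zeros((20, 2)), np.zeros(20))


class TestLevel2Matrix:
    def test_shape_and_fold_counts(self):
        X, y = gaussian_blobs(200)
        Z, folds, fitted = build_level2_matrix(X, y, seed=0)
        assert Z.shape == (200, 5)
        assert set(folds) == {0, 1, 2, 3, 4}
        assert all(len(m) == 5 for m in fitted.values())

    def test_out_of_fold_integrity_with_memorizer(self):
        X, y = gaussian_blobs(100)
        specs = [("probe", _Memorizer())] + default_base_specs(0)[:1]
        Z, _, _ = build_level2_matrix(X, y, specs, seed=1)
        assert np.all(Z[:, 0] == 0.0)

    def test_stratified_folds_balance(self):
        X = np.random.default_rng(0).standard_normal((100, 3))
        y = np.array([1] * 20 + [0] * 80)
        _, folds, _ = build_level2_matrix(
            X, y, [("probe", _Memorizer())], seed=2)
        global_ratio = 0.2
        for f in range(5):
            in_fold = y[folds == f]
            assert abs(in_fold.mean() - global_ratio) <= 1.5 / len(in_fold)

    def test_hand_traced_two_fold_stub(self):
        """With a scorer that always outputs 0.3, every out-of-fold entry
        is exactly 0.3 regardless of the fold pattern."""
        X = np.arange(24, dtype=float).reshape(12, 2)
        y = np.array([0, 1] * 6)
        Z, _, _ = build_level2_matrix(
            X, y, [("stub", _ConstantScorer([0.3]))], n_folds=2, seed=0)
        assert np.allclose(Z[:, 0], 0.3)

    def test_fold_losing_class_refused(self):
        X = np.zeros((12, 2))
        y = np.array([1, 1, 1] + [0] * 9)  # 3 positives < 5 folds
        with pytest.raises(DataError):
            build_level2_matrix(X, y, [("probe", _Memorizer())], n_folds=5)


class TestAveraging:
    def test_identical_fold_models_average_to_same(self):
        fitted = {"stub": [_ConstantScorer([0.7]).fit(np.zeros((2, 2)),
                                                      np.array([0, 1]))
                           for _ in range(5)]}
        Z = average_test_predictions(fitted, np.zeros((3, 2)))
        assert np.allclose(Z, 0.7)

    def test_mean_of_mixed_scores(self):
        models = []
        for v in [0.0, 0.0, 0.0, 0.0, 1.0]:
            models.append(_ConstantScorer([v]).fit(np.zeros((2, 2)),
                                                   np.array([0, 1])))
        Z = average_test_predictions({"stub": models}, np.zeros((4, 2)))
        assert np.allclose(Z, 0.2)

    def test_missing_fold_model_refused(self):
        with pytest.raises(ValidationError):
            average_test_predictions({"a": []}, np.zeros((2, 2)))


class TestFitPredict:
    def test_separable_data_perfect_training_auc(self):
        X, y = gaussian_blobs(120, sep=8.0)
        model = fit_stacking(X, y, seed=0)
        scores = predict(model, X)
        assert roc_auc(scores, y).auc == 1.0

    def test_scores_in_unit_interval_and_deterministic(self):
        X, y = gaussian_blobs(80, sep=1.0)
        model = fit_stacking(X, y, seed=3)
        s1 = predict(model, X)
        s2 = predict(model, X)
        assert np.array_equal(s1, s2)
        assert s1.min() >= 0.0 and s1.max() <= 1.0

    def test_refit_same_seed_reproduces_scores(self):
        X, y = gaussian_blobs(100, sep=1.5)
        a = predict(fit_stacking(X, y, seed=7), X)
        b = predict(fit_stacking(X, y, seed=7), X)
        assert np.allclose(a, b)

    def test_layout_mismatch_refused(self):
        X, y = gaussian_blobs(60)
        model = fit_stacking(X, y, seed=0)
        with pytest.raises(ValidationError):
            predict(model, X[:, :3])

    def test_monotone_meta_preserves_base_ordering(self):
        """With a logistic meta, dominating base scores give a higher
        stacked score."""
        X, y = gaussian_blobs(100, sep=2.0)
        model = fit_stacking(X, y, seed=1)
        meta = model.meta
        assert isinstance(meta, LogisticRegression)
        Z_lo = np.full((1, 5), 0.2)
        Z_hi = np.full((1, 5), 0.8)
        if np.all(meta.coef_ >= 0):
            lo = meta.predict_proba(Z_lo)[0, 1]
            hi = meta.predict_proba(Z_hi)[0, 1]
            assert hi >= lo

    def test_stacked_not_much_worse_than_best_base(self):
        """Median over seeds: stacked AUC >= best single-family
        out-of-fold AUC - 0.02 on a separable-ish benchmark.

        (The label-permutation null of the stack is exercised at full size
        in the acceptance suite.)"""
        deltas = []
        for seed in range(10):
            X, y = gaussian_blobs(160, sep=1.2, seed=seed)
            X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=seed)
            Z, _, fitted = build_level2_matrix(X_tr, y_tr, seed=seed)
            base_aucs = [roc_auc(Z[:, j], y_tr).auc for j in range(5)]
            meta = LogisticRegression(max_iter=2000).fit(Z, y_tr)
            Z_te = average_test_predictions(fitted, X_te)
            stacked = roc_auc(meta.predict_proba(Z_te)[:, 1], y_te).auc
            deltas.append(stacked - max(base_aucs))
        assert np.median(deltas) >= -0.02


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = gaussian_blobs(80, sep=2.0)
        model = fit_stacking(X, y, seed=0)
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        assert np.allclose(predict(loaded, X), predict(model, X))
        assert loaded.base_names == model.base_names
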