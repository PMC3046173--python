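"""Classifier capacity, determinism, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrvrisk.errors import LabelingError
from hrvrisk.classifiers import (
    cross_validate,
    evaluate,
    report_from_confusion,
    roc_auc,
    stratified_split,
    train_mlp,
    train_rbf,
    train_svm,
)


def blobs(seed: int = 0, n: int = 30, sep: float = 3.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(sep, 0.3, (n, 2))])
    y = np.array([0] * n + [1] * n)
    return X, y


def xor_clusters(seed: int = 0, n: int = 15):
    rng = np.random.default_rng(seed)
    centers = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
    X = np.vstack([rng.normal((cx, cy), 0.1, (n, 2)) for cx, cy, _ in centers])
    y = np.repeat([lab for *_, lab in centers], n)
    return X, y


class TestMLP:
    def test_separable_blobs_learned_perfectly(self):
        X, y = blobs()
        model = train_mlp(X, y, hidden=200, seed=0)
        assert (model.predict(X) == y).all()
        assert np.all((model.scores(X) > 0) & (model.scores(X) < 1))

    def test_xor_nonlinear_capacity(self):
        X, y = xor_clusters()
        model = train_mlp(X, y, hidden=20, seed=1)
        assert (model.predict(X) == y).all()

    def test_same_seed_same_predictions(self):
        X, y = blobs(3)
        a = train_mlp(X, y, hidden=50, seed=7)
        b = train_mlp(X, y, hidden=50, seed=7)
        np.testing.assert_array_equal(a.scores(X), b.scores(X))


class TestRBF:
    def test_kmeans_centers_recover_blob_means(self):
        X, y = blobs(1)
        model = train_rbf(X, y, centers=2, seed=0)
        means = np.array([[0, 0], [3, 3]])
        dists = np.linalg.norm(model.centers[:, None] - means[None], axis=2)
        assert dists.min(axis=0).max() < 0.1 * 3  # within 0.1 sigma-scaled sep
        assert (model.predict(X) == y).all()

    def test_interpolation_regime(self):
        X, y = blobs(2, n=10)
        model = train_rbf(X, y, centers=X.shape[0], seed=0)
        assert (model.predict(X) == y).all()

    def test_deterministic_given_seed(self):
        X, y = blobs(4)
        a = train_rbf(X, y, centers=3, seed=5)
        b = train_rbf(X, y, centers=3, seed=5)
        np.testing.assert_array_equal(a.scores(X), b.scores(X))


class TestSVM:
    def test_linear_separable_with_few_support_vectors(self):
        X, y = blobs(5)
        model = train_svm(X, y, kernel="linear", C=1.0)
        assert (model.predict(X) == y).all()
        assert model.n_support_vectors < len(y) / 2

    def test_contradictory_points_bound_training_accuracy(self):
        X = np.vstack([np.zeros((10, 2)), np.zeros((10, 2)), blobs(0, n=5)[0]])
        y = np.array([0] * 10 + [1] * 10 + [0] * 5 + [1] * 5)
        model = train_svm(X, y, kernel="rbf", C=1.0, gamma=0.1)
        contradictory = (model.predict(X[:20]) == y[:20]).mean()
        assert contradictory <= 0.5

    @pytest.mark.parametrize("kernel", ["linear", "poly", "rbf"])
    def test_support_vector_count_reported(self, kernel):
        X, y = blobs(6)
        model = train_svm(X, y, kernel=kernel)
        assert 1 <= model.n_support_vectors <= len(y)


class TestMetrics:
    def test_metric_formulas_on_known_confusion(self):
        rep = report_from_confusion(tp=14, fp=0, tn=15, fn=1)
        assert rep.Se == pytest.approx(93.33, abs=0.01)
        assert rep.Sp == pytest.approx(100.00)
        assert rep.Np == pytest.approx(93.75)
        assert rep.Pp == pytest.approx(100.00)
        assert rep.Ac == pytest.approx(96.67, abs=0.01)

    def test_all_correct_and_symmetric_cases(self):
        perfect = report_from_confusion(tp=15, fp=0, tn=15, fn=0)
        assert perfect.Se == perfect.Sp == perfect.Pp == perfect.Np == perfect.Ac == 100.0
        coin = report_from_confusion(tp=5, fp=5, tn=5, fn=5)
        for name in ("Se", "Sp", "Pp", "Np", "Ac"):
            assert getattr(coin, name) == 50.0

    def test_evaluate_recomputes_identities(self):
        X, y = blobs(7, sep=1.0)
        model = train_svm(X, y, kernel="linear", C=1.0)
        rep = evaluate(model, X, y)
        total = rep.TP + rep.FP + rep.TN + rep.FN
        assert total == len(y)
        assert rep.Ac == pytest.approx(100 * (rep.TP + rep.TN) / total)
        assert rep.n_support_vectors is not None


class TestROC:
    def test_perfect_and_reversed_ordering(self):
        labels = np.array([0] * 10 + [1] * 10)
        scores = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)
        _, auc_rev = roc_auc(-scores, labels)
        assert auc_rev == pytest.approx(0.0)

    def test_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, 200)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            expected = u / ((labels == 1).sum() * (labels == 0).sum())
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(LabelingError):
            roc_auc(np.arange(5.0), np.ones(5, dtype=int))


class TestSplitAndCV:
    def test_balanced_90_record_split_shape(self):
        labels = np.array(["N"] * 45 + ["R"] * 45)
        plan = stratified_split(labels, seed=3)
        assert plan.train_ids.size == 60 and plan.test_ids.size == 30
        assert (labels[plan.train_ids] == "N").sum() == 30
        assert (labels[plan.test_ids] == "R").sum() == 15

    def test_split_reproducible(self):
        labels = np.array([0] * 45 + [1] * 45)
        a = stratified_split(labels, seed=9)
        b = stratified_split(labels, seed=9)
        np.testing.assert_array_equal(a.train_ids, b.train_ids)

    def test_cross_validate_on_strong_effect(self):
        X, y = blobs(8, n=45, sep=2.0)
        table = pd.DataFrame(X, columns=["f1", "f2"])
        reports = cross_validate(table, y, scheme="svm-linear", seed=1, repeats=3)
        assert len(reports) == 3
        assert np.mean([r.Ac for r in reports]) >= 90.0
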