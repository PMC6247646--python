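"""Classifier and metrics: one-vs-all SVM behavior, LOOCV against an
exhaustive oracle, the confusion-matrix identities, ROC/AUC against a
concordance oracle, and the KS statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motormap import evaluate
from motormap.evaluate import (
    ConfusionMatrix,
    accuracy,
    grand_average_confusion,
    ks_compare,
    ks_normality,
    loocv,
    osr,
    quality_ratio,
    roc_auc_bootstrap,
    success_rate,
    train_svm,
)


@pytest.fixture(scope="module")
def separable_clusters():
    rng = np.random.default_rng(0)
    pts = np.vstack([rng.standard_normal((20, 2)) + c
                     for c in ((0, 0), (6, 0), (0, 6))])
    labels = np.array(["S_H"] * 20 + ["S_PD"] * 20 + ["S_DBS"] * 20)
    return pts, labels


class TestSVM:
    def test_separable_training_error_zero(self, separable_clusters):
        pts, labels = separable_clusters
        model = train_svm(pts, labels)
        assert (model.predict(pts) == labels).all()

    def test_order_invariance(self, separable_clusters):
        pts, labels = separable_clusters
        perm = np.random.default_rng(1).permutation(len(pts))
        a = train_svm(pts, labels).predict(pts)
        b = train_svm(pts[perm], labels[perm]).predict(pts)
        np.testing.assert_array_equal(a, b)

    def test_xor_layout_nonlinear_boundary(self):
        rng = np.random.default_rng(2)
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 8, float)
        pts = base + 0.05 * rng.standard_normal(base.shape)
        labels = np.where(base[:, 0] != base[:, 1], "S_H", "S_PD")
        model = train_svm(pts, labels)
        assert (model.predict(pts) == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), ["S_H"] * 5)


class TestLOOCV:
    def test_separable_diagonal_confusion(self, separable_clusters):
        pts, labels = separable_clusters
        cm, rtp = loocv(pts, labels)
        assert np.trace(cm.counts) == cm.tns
        assert all(v == 1.0 for v in rtp.values())

    def test_four_sample_exhaustive_oracle(self):
        """n = 4: LOOCV equals manually enumerating the 4 refits."""
        pts = np.array([[0, 0], [0.4, 0], [5, 5], [5.2, 4.8]])
        labels = np.array(["S_H", "S_H", "S_PD", "S_PD"])
        cm, _ = loocv(pts, labels)
        manual = []
        for i in range(4):
            mask = np.arange(4) != i
            model = train_svm(pts[mask], labels[mask])
            manual.append(model.predict(pts[i:i + 1])[0])
        expected = ConfusionMatrix.from_predictions(labels, manual)
        np.testing.assert_array_equal(cm.counts, expected.counts)

    def test_shuffled_labels_near_chance(self, separable_clusters):
        pts, labels = separable_clusters
        shuffled = np.random.default_rng(3).permutation(labels)
        cm, _ = loocv(pts, shuffled)
        assert osr(cm) / 100 == pytest.approx(1 / 3, abs=0.15)

    def test_fold_losing_a_class_flagged(self):
        pts = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5], [9, 0]])
        labels = np.array(["S_H", "S_H", "S_PD", "S_PD", "S_DBS"])
        with pytest.warns(UserWarning, match="lost a class"):
            cm, _ = loocv(pts, labels)
        assert cm.tns == 5


class TestMetrics:
    def test_accuracy_formula(self):
        counts = np.array([[45, 5, 5], [10, 50, 0], [6, 0, 50]])
        cm = ConfusionMatrix(counts)
        assert cm.tp("S_H") == 45 and cm.fp("S_H") == 10
        assert cm.fn("S_H") == 16 and cm.tn("S_H") == 100
        assert accuracy(cm, "S_H") == pytest.approx(145 / 171)

    def test_osr_identity_and_zero(self):
        assert osr(ConfusionMatrix(np.eye(3, dtype=int) * 10)) == 100.0
        off = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        assert osr(ConfusionMatrix(off)) == 0.0

    def test_osr_arithmetic(self):
        counts = np.diag([44, 71, 51])
        counts[0, 1] = 5
        cm = ConfusionMatrix(counts)
        assert cm.tns == 171
        assert osr(cm) == pytest.approx(100 * 166 / 171)

    def test_success_rate_mean(self):
        grid = np.array([1.0] * 14 + [0.0] * 14)
        assert success_rate(grid) == 0.5
        rng = np.random.default_rng(4)
        r = rng.uniform(size=28)
        assert success_rate(r) == pytest.approx(r.mean())

    def test_quality_ratio_values(self):
        assert quality_ratio(100, 100) == 100
        assert quality_ratio(0, 0) == 0
        assert quality_ratio(96.9, 76.6) == pytest.approx(86.75)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_quality_ratio_symmetric(self, a, b):
        assert quality_ratio(a, b) == quality_ratio(b, a)

    def test_confusion_count_identities(self, separable_clusters):
        pts, labels = separable_clusters
        cm, _ = loocv(pts, labels)
        for c in cm.classes:
            assert cm.tp(c) + cm.tn(c) + cm.fp(c) + cm.fn(c) == cm.tns

    def test_grand_average_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        cms = [ConfusionMatrix(rng.integers(1, 20, (3, 3))) for _ in range(4)]
        avg = grand_average_confusion(cms)
        np.testing.assert_allclose(avg.sum(axis=0), 1.0, atol=1e-9)


class TestROC:
    def test_perfect_separation(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.concatenate([np.zeros(10), np.ones(10)]).astype(int)
        out = roc_auc_bootstrap(scores, y, replicas=50, seed=0)
        assert out["auc"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        out = roc_auc_bootstrap(rng.uniform(size=500),
                                rng.integers(0, 2, 500), replicas=100, seed=0)
        assert out["auc"] == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_concordance_count(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(30)
        y = rng.integers(0, 2, 30)
        pos, neg = scores[y == 1], scores[y == 0]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        out = roc_auc_bootstrap(scores, y, replicas=10, seed=0)
        assert out["auc"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_degenerate_scores_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = roc_auc_bootstrap(np.ones(20), np.tile([0, 1], 10),
                                    replicas=10, seed=0)
        assert out["auc"] == 0.5 and out["flagged"]

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)])
        y = np.repeat([0, 1], 50)
        out = roc_auc_bootstrap(scores, y, replicas=300, seed=1)
        lo, hi = out["ci"]
        assert lo <= out["auc"] <= hi


class TestKS:
    def test_identical_samples(self):
        x = np.arange(10.0)
        stat, p = ks_compare(x, x)
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        a = np.random.default_rng(9).uniform(0, 1, 50)
        b = a + 10
        stat, p = ks_compare(a, b)
        assert stat == 1.0 and p < 1e-6

    def test_statistic_equals_max_ecdf_gap(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 0.5
        stat, _ = ks_compare(a, b)
        grid = np.sort(np.concatenate([a, b]))
        gaps = [abs((a <= g).mean() - (b <= g).mean()) for g in grid]
        assert stat == pytest.approx(max(gaps), abs=1e-12)

    def test_normality_check_runs(self):
        x = np.random.default_rng(11).standard_normal(50)
        stat, p = ks_normality(x)
        assert 0 <= stat <= 1 and p > 0.01
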