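"""Embeddings: PCA identities, perplexity calibration, the KL objective
and its gradient, Sammon stress descent, and the nonlinear-structure
advantage of t-SNE over PCA."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from motormap import dimred
from motormap.dimred import (
    kl_cost,
    lowdim_affinities,
    pca_project,
    perplexity_calibration,
    sammon_map,
    tsne_gradient,
    tsne_map,
)


def _loo_1nn_accuracy(points, labels):
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    return (labels[D.argmin(axis=1)] == labels).mean()


class TestPCA:
    def test_line_in_5d_explains_everything(self):
        t = np.linspace(-1, 1, 30)[:, None]
        X = t @ np.array([[1.0, -2.0, 0.5, 3.0, 1.5]])
        _, _, evr = pca_project(X, 1)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_shares(self):
        X = np.random.default_rng(0).standard_normal((200, 4))
        _, _, evr = pca_project(X, 4)
        np.testing.assert_allclose(evr, 0.25, atol=0.05)

    def test_scores_equal_centered_projection(self):
        X = np.random.default_rng(1).standard_normal((40, 6))
        scores, loadings, _ = pca_project(X, 3)
        np.testing.assert_allclose(scores, (X - X.mean(0)) @ loadings,
                                   atol=1e-10)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(3), atol=1e-10)

    def test_rank_deficient_k_truncated(self):
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10)
        with pytest.warns(UserWarning, match="rank"):
            scores, _, _ = pca_project(X, 3)
        assert scores.shape[1] == 1


class TestPerplexityCalibration:
    def test_two_points_forced_normalization(self):
        model = perplexity_calibration(np.array([[0.0, 4.0], [4.0, 0.0]]), 1.5)
        np.testing.assert_allclose(model.conditional,
                                   np.array([[0, 1], [1, 0]]), atol=1e-12)

    def test_equidistant_points_uniform_rows(self):
        n = 6
        d2 = np.ones((n, n)) - np.eye(n)
        model = perplexity_calibration(d2, 3.0)
        off = model.conditional[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1 / (n - 1), atol=1e-10)

    def test_achieved_perplexity_within_tolerance(self):
        X = np.random.default_rng(4).standard_normal((10, 3))
        model = perplexity_calibration(squareform(pdist(X, "sqeuclidean")), 5.0)
        for i in range(10):
            p = model.conditional[i][model.conditional[i] > 0]
            h = -np.sum(p * np.log2(p))
            assert 2**h == pytest.approx(5.0, abs=1e-3)

    def test_joint_matrix_invariants(self):
        X = np.random.default_rng(5).standard_normal((12, 4))
        model = perplexity_calibration(squareform(pdist(X, "sqeuclidean")), 4.0)
        P = model.joint
        assert P.sum() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert np.all(np.diag(P) == 0)


class TestKLCost:
    def test_identity_zero(self):
        P = np.full((3, 3), 1 / 9)
        assert kl_cost(P, P) == pytest.approx(0.0, abs=1e-14)

    def test_hand_arithmetic_ln2(self):
        assert kl_cost(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == (
            pytest.approx(np.log(2))
        )

    def test_matches_elementwise_sum(self):
        rng = np.random.default_rng(6)
        P = rng.uniform(size=(5, 5)); P /= P.sum()
        Q = rng.uniform(size=(5, 5)); Q /= Q.sum()
        brute = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j])
            for i in range(5) for j in range(5)
        )
        assert kl_cost(P, Q) == pytest.approx(brute, rel=1e-12)

    def test_degenerate_q_rejected(self):
        with pytest.raises(ValueError):
            kl_cost(np.array([0.5, 0.5]), np.array([1.0, 0.0]))


class TestTsne:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((7, 4))
        model = perplexity_calibration(squareform(pdist(X, "sqeuclidean")), 3.0)
        P = np.maximum(model.joint, 1e-12)
        P /= P.sum()
        Y = rng.standard_normal((7, 2))
        grad = tsne_gradient(P, Y)
        num = np.zeros_like(Y)
        eps = 1e-6
        for i in range(7):
            for j in range(2):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, j] += eps
                Ym[i, j] -= eps
                cp = kl_cost(P, np.maximum(lowdim_affinities(Yp)[0], 1e-12))
                cm = kl_cost(P, np.maximum(lowdim_affinities(Ym)[0], 1e-12))
                num[i, j] = (cp - cm) / (2 * eps)
        assert np.max(np.abs(grad - num)) / np.max(np.abs(num)) < 1e-5

    def test_three_clusters_perfect_neighborhoods(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.standard_normal((20, 10)) + c for c in (0, 8, 16)])
        labels = np.repeat([0, 1, 2], 20)
        emb = tsne_map(X, iterations=600, learning_rate=200, perplexity=10,
                       seed=1)
        assert _loo_1nn_accuracy(emb.coordinates, labels) == 1.0

    def test_cost_non_increasing_at_the_end(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.standard_normal((15, 6)) + c for c in (0, 6)])
        emb = tsne_map(X, iterations=500, learning_rate=100, perplexity=8,
                       seed=2)
        tail = emb.cost_trace[-100:]
        assert np.all(np.diff(tail) <= 1e-6)

    def test_reproducible_given_seed(self):
        X = np.random.default_rng(10).standard_normal((20, 5))
        a = tsne_map(X, iterations=120, learning_rate=100, perplexity=6, seed=3)
        b = tsne_map(X, iterations=120, learning_rate=100, perplexity=6, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestSammon:
    def test_already_2d_is_isometry(self):
        X = np.random.default_rng(11).standard_normal((10, 2))
        emb = sammon_map(X, iterations=50)
        assert emb.final_cost <= 1e-6

    def test_planar_square_in_3d_exactly_embeddable(self):
        plane = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float) @ plane
        emb = sammon_map(X, iterations=100)
        assert emb.final_cost <= 1e-6

    def test_accepted_stress_non_increasing(self):
        X = np.random.default_rng(12).standard_normal((25, 8))
        emb = sammon_map(X, iterations=80)
        assert np.all(np.diff(emb.cost_trace) <= 1e-15)

    def test_duplicate_rows_jittered(self):
        X = np.vstack([np.zeros(3), np.zeros(3),
                       np.random.default_rng(13).standard_normal((6, 3))])
        emb = sammon_map(X, iterations=30)
        assert np.all(np.isfinite(emb.coordinates))


def test_tsne_beats_pca_when_variance_is_nuisance():
    """Clusters living in low-variance directions under a dominant
    nuisance plane: the top-2 linear projection scrambles neighborhoods
    while t-SNE's local affinities preserve them."""
    rng = np.random.default_rng(14)
    k, per = 6, 10
    centers = np.zeros((k, 10))
    sub = rng.standard_normal((k, 8))
    centers[:, 2:] = 4 * sub / np.linalg.norm(sub, axis=1, keepdims=True)
    X = np.vstack([centers[i] + 0.3 * rng.standard_normal((per, 10))
                   for i in range(k)])
    X[:, :2] += 3.0 * rng.standard_normal((k * per, 2))
    labels = np.repeat(np.arange(k), per)

    pca_scores = pca_project(X, 2)[0]
    emb = tsne_map(X, iterations=700, learning_rate=150, perplexity=8, seed=4)
    assert _loo_1nn_accuracy(emb.coordinates, labels) > (
        _loo_1nn_accuracy(pca_scores, labels) + 0.3
    )
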