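"""Two-dimensional embeddings: PCA, Sammon's mapping, and t-SNE.

Sammon's mapping and t-SNE are implemented from their defining
objectives.  t-SNE minimizes the Kullback–Leibler divergence between
Gaussian high-dimensional affinities (per-point bandwidths calibrated to
a target perplexity by bisection) and Student-t (1 d.o.f.)
low-dimensional affinities, by gradient descent with momentum, adaptive
per-parameter gains and early exaggeration.  Sammon's mapping minimizes
the inverse-distance-weighted stress with the classical diagonal-Newton
update, PCA initialization and step-halving on stress increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

_EPS = 1e-12


@dataclass
class AffinityModel:
    """Perplexity-calibrated Gaussian affinities of a point set.

    ``conditional`` holds the row-stochastic p(j|i); ``joint`` the
    symmetrized P = (p(j|i) + p(i|j)) / 2n; ``sigmas`` the per-point
    Gaussian bandwidths; ``perplexity`` the calibration target.
    """

    conditional: np.ndarray
    joint: np.ndarray
    sigmas: np.ndarray
    perplexity: float
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        n = self.conditional.shape[0]
        assert np.allclose(self.conditional.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(self.joint, self.joint.T, atol=1e-12)
        assert abs(self.joint.sum() - 1.0) < 1e-8
        assert np.all(np.diag(self.conditional) == 0)
        assert np.all(self.joint >= 0) and n == self.joint.shape[0]


@dataclass
class Embedding:
    """A 2-D map of a sample set plus the method and final cost.

    ``final_cost`` is the KL divergence for t-SNE, the stress for
    Sammon's mapping, and 1 − retained-variance fraction context is
    not used: for PCA it stores the retained-variance fraction.
    """

    coordinates: np.ndarray
    method: str
    iterations: int = 0
    learning_rate: float = 0.0
    perplexity: float | None = None
    final_cost: float = 0.0
    seed: int | None = None
    cost_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("embedding coordinates must be n × 2")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


# ---------------------------------------------------------------------------
# PCA

def pca_project(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components via SVD of the centered data.

    Returns ``(scores, loadings, explained_variance_fractions)`` with
    orthonormal loadings (d × k) and a deterministic sign convention
    (largest-magnitude element of each loading positive).  ``k`` beyond
    the data rank is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= k < n:
        raise ValueError("need rows > k >= 1")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0) * max(n, d) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds data rank {rank}; truncated", stacklevel=2)
        k = max(rank, 1)
    var = S**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    loadings = Vt[:k].T
    # Deterministic signs for reproducible plots.
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    return scores, loadings, evr


# ---------------------------------------------------------------------------
# Affinities and KL cost

def _row_affinity(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Gaussian affinities at precision beta and their entropy in bits."""
    p = np.exp(-d2_row * beta)
    s = p.sum()
    if s <= 0:
        return np.full_like(p, 1.0 / p.size), np.log2(p.size)
    p /= s
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return p, h


def perplexity_calibration(d2: np.ndarray, perplexity: float, *,
                           tol: float = 1e-4, max_iter: int = 200) -> AffinityModel:
    """Per-point bandwidth bisection so that 2^H(p(·|i)) hits the target.

    ``d2`` is the full matrix of pairwise *squared* distances.  When the
    target is unattainable for a point (degenerate distances), the
    closest attainable distribution is used and the point flagged.
    """
    d2 = np.asarray(d2, dtype=float)
    n = d2.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if perplexity >= n:
        raise ValueError("perplexity must be below the number of points")
    target_h = np.log2(perplexity)
    cond = np.zeros((n, n))
    sigmas = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        idx = np.arange(n) != i
        row = d2[i, idx]
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p, h = _row_affinity(row, beta)
        it = 0
        while abs(h - target_h) > tol and it < max_iter:
            if h > target_h:        # too many effective neighbors
                beta_lo = beta
                beta = beta * 2 if not np.isfinite(beta_hi) else (beta + beta_hi) / 2
            else:
                beta_hi = beta
                beta = (beta + beta_lo) / 2
            p, h = _row_affinity(row, beta)
            it += 1
        if abs(h - target_h) > tol:
            flagged[i] = True
        cond[i, idx] = p
        sigmas[i] = np.sqrt(1.0 / (2 * beta)) if beta > 0 else np.inf
    joint = (cond + cond.T) / (2 * n)
    return AffinityModel(conditional=cond, joint=joint, sigmas=sigmas,
                         perplexity=perplexity, flagged=flagged)


def kl_cost(P: np.ndarray, Q: np.ndarray) -> float:
    """Σ p log(p/q) (natural log); errors where q = 0 at p > 0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError("q = 0 where p > 0: degenerate embedding")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def lowdim_affinities(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t (1 d.o.f.) joint affinities Q and the kernel matrix
    W = 1/(1+||y_i−y_j||²) with zero diagonal."""
    d2 = squareform(pdist(Y, "sqeuclidean"))
    W = 1.0 / (1.0 + d2)
    np.fill_diagonal(W, 0.0)
    Q = W / max(W.sum(), _EPS)
    return Q, W


def tsne_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic t-SNE gradient 4 Σ_j (p_ij − q_ij) w_ij (y_i − y_j)."""
    Q, W = lowdim_affinities(Y)
    M = (P - Q) * W
    # grad_i = 4 * sum_j M_ij (y_i - y_j)
    return 4.0 * (np.diag(M.sum(axis=1)) @ Y - M @ Y)


def tsne_map(X: np.ndarray, iterations: int = 1000, learning_rate: float = 200.0,
             perplexity: float = 30.0, seed: int = 0, *,
             momentum: tuple[float, float] = (0.5, 0.8),
             momentum_switch: int = 250, exaggeration: float = 4.0,
             exaggeration_iters: int = 100, init_sd: float = 1e-4,
             min_gain: float = 0.01, monotone_final_iters: int = 100,
             init: str = "pca") -> Embedding:
    """t-SNE by gradient descent on the KL objective.

    Gaussian init (sd ``init_sd``), early exaggeration of P for the
    first ``exaggeration_iters`` iterations, momentum switching at
    ``momentum_switch``, and per-parameter adaptive gains.  During the
    last ``monotone_final_iters`` iterations the optimizer switches to a
    backtracking phase: a step that would raise the cost is rejected,
    the local step scale halved and the momentum reset, so the accepted
    cost trace is non-increasing at the end of the run.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points")
    model = perplexity_calibration(squareform(pdist(X, "sqeuclidean")), perplexity)
    P = np.maximum(model.joint, _EPS)
    P /= P.sum()

    rng = np.random.default_rng(seed)
    if init == "pca":
        # PCA init rescaled to the usual small starting spread keeps the
        # map globally organized (and easier to extend out of sample).
        scores = pca_project(X, 2)[0]
        sd0 = scores[:, 0].std()
        Y = scores * (init_sd / sd0 if sd0 > 0 else 1.0)
        Y = Y + 0.1 * init_sd * rng.standard_normal((n, 2))
    elif init == "random":
        Y = init_sd * rng.standard_normal((n, 2))
    else:
        raise ValueError("init must be 'pca' or 'random'")
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    trace = np.empty(iterations)

    def _cost(Yc):
        Q, _ = lowdim_affinities(Yc)
        return kl_cost(P, np.maximum(Q, _EPS))

    cost = np.inf
    scale = 1.0
    monotone_from = max(iterations - monotone_final_iters, exaggeration_iters)
    for it in range(iterations):
        Pe = P * exaggeration if it < exaggeration_iters else P
        grad = tsne_gradient(Pe, Y)
        mom = momentum[0] if it < momentum_switch else momentum[1]
        gains = np.where(np.sign(grad) != np.sign(dY), gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, min_gain)
        if it < monotone_from:
            dY = mom * dY - learning_rate * gains * grad
            Y = Y + dY
            Y = Y - Y.mean(axis=0)
            cost = _cost(Y)
        else:
            # Backtracking finish: never accept a cost increase.
            accepted = False
            for _ in range(30):
                step = mom * dY - scale * learning_rate * gains * grad
                c_new = _cost(Y + step)
                if c_new <= cost:
                    dY = step
                    Y = Y + step
                    Y = Y - Y.mean(axis=0)
                    cost = c_new
                    scale = min(scale * 1.1, 1.0)
                    accepted = True
                    break
                scale /= 2.0
                dY = np.zeros_like(dY)
                mom = 0.0
            if not accepted:
                cost = _cost(Y)  # converged: keep current embedding
        if not np.isfinite(cost):
            raise FloatingPointError(
                f"t-SNE cost diverged at iteration {it}; reduce the learning rate"
            )
        trace[it] = cost

    return Embedding(coordinates=Y, method="t-SNE", iterations=iterations,
                     learning_rate=learning_rate, perplexity=perplexity,
                     final_cost=float(trace[-1]), seed=seed, cost_trace=trace)


# ---------------------------------------------------------------------------
# Sammon's mapping

def sammon_stress(dstar: np.ndarray, d: np.ndarray) -> float:
    """Σ[(d*−d)²/d*] / Σd* over unordered pairs (condensed vectors)."""
    return float(np.sum((dstar - d) ** 2 / dstar) / dstar.sum())


def sammon_map(X: np.ndarray, iterations: int = 100, learning_rate: float = 0.4,
               *, jitter: float = 1e-10, tol: float = 1e-12,
               plain_gradient: bool = False, seed: int = 0) -> Embedding:
    """Sammon's mapping by diagonal-Newton descent with PCA init.

    ``learning_rate`` is the classical step ("magic") factor applied to
    the Newton step; a stress increase triggers step-halving (up to 20
    halvings) so accepted stress is non-increasing.  Duplicate input
    points are jittered by ``jitter``; exact duplicates after jitter are
    an error.  ``plain_gradient=True`` uses raw gradient descent.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    dstar_c = pdist(X)
    if np.any(dstar_c == 0):
        rng = np.random.default_rng(seed)
        X = X + jitter * rng.standard_normal(X.shape)
        dstar_c = pdist(X)
        if np.any(dstar_c == 0):
            raise ValueError("duplicate rows remain after jitter")
    dstar = squareform(dstar_c)
    c = dstar_c.sum()

    if X.shape[1] >= 2 and n > 2:
        Y = pca_project(X, 2)[0]
    else:
        Y = np.column_stack([X[:, 0], np.zeros(n)])
    # Collapsed init (e.g. rank-deficient X) gets a deterministic spread.
    if np.any(pdist(Y) == 0):
        rng = np.random.default_rng(seed)
        Y = Y + 1e-6 * rng.standard_normal(Y.shape)

    stress = sammon_stress(dstar_c, pdist(Y))
    trace = [stress]
    for _ in range(iterations):
        diff = Y[:, None, :] - Y[None, :, :]           # n × n × 2
        d = squareform(pdist(Y))
        np.fill_diagonal(d, 1.0)
        dst = dstar.copy()
        np.fill_diagonal(dst, 1.0)
        inv = 1.0 / (d * dst)
        np.fill_diagonal(inv, 0.0)
        delta = dstar - d
        g = (-2.0 / c) * np.einsum("ij,ijk->ik", delta * inv, diff)
        if plain_gradient:
            step = -g
        else:
            h_term = delta * inv - (diff**2).transpose(2, 0, 1) * inv / d * (
                1.0 + delta / d
            )
            # Diagonal of the Hessian, per coordinate.
            H = (-2.0 / c) * np.einsum("kij->ik", h_term)
            step = -g / np.maximum(np.abs(H), _EPS)
        eta = learning_rate
        accepted = False
        for _ in range(20):
            Y_new = Y + eta * step
            d_new = pdist(Y_new)
            if np.all(d_new > 0):
                s_new = sammon_stress(dstar_c, d_new)
                if s_new <= stress:
                    Y, stress = Y_new, s_new
                    accepted = True
                    break
            eta /= 2.0
        trace.append(stress)
        if not accepted or (len(trace) > 1 and trace[-2] - trace[-1] < tol):
            break

    return Embedding(coordinates=Y, method="Sammon", iterations=iterations,
                     learning_rate=learning_rate, final_cost=float(stress),
                     seed=seed, cost_trace=np.asarray(trace))
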