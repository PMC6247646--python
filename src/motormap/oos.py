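"""Parametric out-of-sample extension of a learned 2-D embedding.

Nonlinear embeddings (Sammon, t-SNE) map only the training set; held-out
samples are placed by a learned mapping f: x → y.  The training features
first pass through a linear projection retaining at least 90% of the
total variance, then a small feedforward regression network (one hidden
tanh layer, linear 2-unit output) is fit to the training embedding
coordinates.

Training uses Levenberg–Marquardt least squares with Bayesian-evidence
re-estimation of the weight-decay coefficient (MacKay's update): the
objective is β·E_D + α·E_W with E_D = ½Σe², E_W = ½Σw², and after each
accepted step the effective number of parameters
γ = N_w − α·tr(H⁻¹) refreshes α = γ/(2E_W) and β = (N − γ)/(2E_D).
``hidden_units=0`` degenerates to a linear network, fit the same way
(equivalent to ridge regression at fixed α/β).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dimred import pca_project


@dataclass
class _Network:
    """Weights of the regression network (or a linear map if W1 is None).

    The hidden-layer variant carries a linear bypass ``Ws``: the output
    is ``Z @ Ws + tanh(Z @ W1 + b1) @ W2 + b2``, so a (near-)linear
    target is representable with small weights and the tanh units model
    only the nonlinear residual — the weight-decay prior then yields
    sane extrapolation on linear structure.
    """

    W1: np.ndarray | None   # (k, h)
    b1: np.ndarray | None   # (h,)
    W2: np.ndarray          # (h or k, 2)
    b2: np.ndarray          # (2,)
    Ws: np.ndarray | None = None  # (k, 2) linear bypass

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.W1 is None:
            return Z @ self.W2 + self.b2
        out = np.tanh(Z @ self.W1 + self.b1) @ self.W2 + self.b2
        if self.Ws is not None:
            out = out + Z @ self.Ws
        return out


@dataclass
class OOSMapper:
    """Variance-preserving projection + trained regression network."""

    pca_mean: np.ndarray
    pca_loadings: np.ndarray      # (d, k)
    retained_variance: float
    network: _Network
    mse: float = np.nan
    r_value: float = np.nan
    alpha: float = np.nan
    beta: float = np.nan

    def __post_init__(self) -> None:
        if self.retained_variance < 0.90 - 1e-12:
            raise ValueError("projection must retain >= 90% of variance")

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.pca_mean) @ self.pca_loadings


def _unpack(theta: np.ndarray, k: int, h: int) -> _Network:
    if h == 0:
        W2 = theta[: k * 2].reshape(k, 2)
        b2 = theta[k * 2:]
        return _Network(None, None, W2, b2)
    i = 0
    W1 = theta[i:i + k * h].reshape(k, h); i += k * h
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + h * 2].reshape(h, 2); i += h * 2
    b2 = theta[i:i + 2]; i += 2
    Ws = theta[i:].reshape(k, 2)
    return _Network(W1, b1, W2, b2, Ws)


def _jacobian(theta: np.ndarray, Z: np.ndarray, k: int, h: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Residual-model Jacobian d(vec outputs)/d(theta) and predictions.

    Outputs are ordered sample-major, coordinate-minor (n × 2 flattened
    row-wise).
    """
    n = Z.shape[0]
    net = _unpack(theta, k, h)
    if h == 0:
        pred = net.predict(Z)
        J = np.zeros((2 * n, theta.size))
        # d y_c / d W2[j, c] = Z[:, j]; d y_c / d b2[c] = 1
        for c in range(2):
            for j in range(k):
                J[c::2, j * 2 + c] = Z[:, j]
            J[c::2, k * 2 + c] = 1.0
        return J, pred
    A = Z @ net.W1 + net.b1          # (n, h)
    T = np.tanh(A)
    dT = 1.0 - T**2
    pred = T @ net.W2 + net.b2 + Z @ net.Ws
    J = np.zeros((2 * n, theta.size))
    skip0 = k * h + h + h * 2 + 2
    for c in range(2):
        rows = slice(c, 2 * n, 2)
        back = dT * net.W2[:, c]                     # (n, h)
        # W1 block: d y_c / d W1[j, u] = Z[:, j] * back[:, u]
        JW1 = (Z[:, :, None] * back[:, None, :]).reshape(n, k * h)
        J[rows, : k * h] = JW1
        J[rows, k * h: k * h + h] = back             # b1
        J[rows, k * h + h + np.arange(h) * 2 + c] = T  # W2[:, c]
        J[rows, k * h + h + h * 2 + c] = 1.0         # b2
        J[rows, skip0 + np.arange(k) * 2 + c] = Z    # Ws[:, c]
    return J, pred


def fit_oos_mapper(X_train: np.ndarray, Y_train: np.ndarray, *,
                   variance_kept: float = 0.90, hidden_units: int = 20,
                   max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
                   alpha0: float | None = None, beta0: float | None = None,
                   update_evidence: bool = True) -> OOSMapper:
    """Fit the projection and the regression network to embedding targets.

    ``alpha0``/``beta0`` fix the initial regularization and noise
    precisions; with ``update_evidence=False`` they stay fixed (useful
    to compare the linear network against closed-form ridge with
    λ = α/β).
    """
    X = np.asarray(X_train, dtype=float)
    Y = np.asarray(Y_train, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X_train and Y_train must be row-aligned")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite embedding targets")

    n, d = X.shape
    _, loadings, evr = pca_project(X, min(n - 1, d))
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, loadings.shape[1])
    retained = float(cum[k - 1])
    mean = X.mean(axis=0)
    loadings = loadings[:, :k]
    Z = (X - mean) @ loadings

    h = hidden_units
    rng = np.random.default_rng(seed)
    if h == 0:
        theta = np.zeros(k * 2 + 2)
    else:
        # Linear-first initialization: the bypass starts at the ridge
        # solution and the tanh output weights at zero, so the hidden
        # units only grow where the residual demands nonlinearity.
        W_ridge = np.linalg.solve(
            Z.T @ Z + 1e-3 * np.eye(Z.shape[1]), Z.T @ (Y - Y.mean(axis=0))
        )
        theta = np.concatenate([
            rng.uniform(-1, 1, k * h) / np.sqrt(k),
            np.zeros(h),
            np.zeros(h * 2),
            Y.mean(axis=0),
            W_ridge.ravel(),
        ])

    target = Y.reshape(-1)  # row-major: sample-major, coord-minor
    N = target.size
    Np = theta.size
    alpha = 1e-2 if alpha0 is None else float(alpha0)
    beta = 1.0 if beta0 is None else float(beta0)
    mu = 1e-3

    def objective(th, e):
        return beta * 0.5 * np.sum(e**2) + alpha * 0.5 * np.sum(th**2)

    J, pred = _jacobian(theta, Z, k, h)
    e = pred.reshape(-1) - target
    F = objective(theta, e)
    for _ in range(max_iter):
        g = beta * (J.T @ e) + alpha * theta
        H = beta * (J.T @ J) + alpha * np.eye(Np)
        improved = False
        for _ in range(30):
            try:
                step = np.linalg.solve(H + mu * np.eye(Np), -g)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            th_new = theta + step
            _, pred_new = _jacobian(th_new, Z, k, h)
            e_new = pred_new.reshape(-1) - target
            F_new = objective(th_new, e_new)
            if F_new < F:
                theta, e, F = th_new, e_new, F_new
                J, pred = _jacobian(theta, Z, k, h)
                mu = max(mu / 10, 1e-12)
                improved = True
                break
            mu *= 10
        if not improved:
            break
        F_prev = F
        if update_evidence:
            H = beta * (J.T @ J) + alpha * np.eye(Np)
            gamma = Np - alpha * np.trace(np.linalg.inv(H))
            ew = 0.5 * np.sum(theta**2)
            ed = 0.5 * np.sum(e**2)
            alpha = float(gamma / max(2 * ew, 1e-12))
            beta = float(max(N - gamma, 1e-3) / max(2 * ed, 1e-12))
            F = objective(theta, e)
        if abs(F_prev - F) < tol and np.linalg.norm(g) < 1e-4:
            break

    net = _unpack(theta, k, h)
    fitted = net.predict(Z)
    resid = fitted - Y
    mse = float(np.mean(resid**2))
    yf, ff = Y.reshape(-1), fitted.reshape(-1)
    denom = np.std(yf) * np.std(ff)
    r = float(np.corrcoef(yf, ff)[0, 1]) if denom > 0 else 0.0
    return OOSMapper(
        pca_mean=mean, pca_loadings=loadings, retained_variance=retained,
        network=net, mse=mse, r_value=r, alpha=alpha, beta=beta,
    )


def apply_oos(mapper: OOSMapper, X_new: np.ndarray) -> np.ndarray:
    """Map new standardized feature vectors to 2-D coordinates."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.empty((0, 2))
    if X_new.ndim != 2 or X_new.shape[1] != mapper.pca_loadings.shape[0]:
        raise ValueError("feature-count mismatch with the fitted mapper")
    return mapper.network.predict(mapper.project(X_new))


def save_mapper(mapper: OOSMapper, path: str | Path) -> None:
    """Serialize a mapper as JSON (+ arrays as nested lists)."""
    net = mapper.network
    Path(path).write_text(json.dumps(dict(
        pca_mean=mapper.pca_mean.tolist(),
        pca_loadings=mapper.pca_loadings.tolist(),
        retained_variance=mapper.retained_variance,
        W1=None if net.W1 is None else net.W1.tolist(),
        b1=None if net.b1 is None else net.b1.tolist(),
        W2=net.W2.tolist(), b2=net.b2.tolist(),
        Ws=None if net.Ws is None else net.Ws.tolist(),
        mse=mapper.mse, r_value=mapper.r_value,
        alpha=mapper.alpha, beta=mapper.beta,
    )))


def load_mapper(path: str | Path) -> OOSMapper:
    d = json.loads(Path(path).read_text())
    net = _Network(
        W1=None if d["W1"] is None else np.array(d["W1"]),
        b1=None if d["b1"] is None else np.array(d["b1"]),
        W2=np.array(d["W2"]), b2=np.array(d["b2"]),
        Ws=None if d.get("Ws") is None else np.array(d["Ws"]),
    )
    return OOSMapper(
        pca_mean=np.array(d["pca_mean"]),
        pca_loadings=np.array(d["pca_loadings"]),
        retained_variance=d["retained_variance"], network=net,
        mse=d["mse"], r_value=d["r_value"], alpha=d["alpha"], beta=d["beta"],
    )
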