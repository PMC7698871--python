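"""Localized least-squares support-vector regression (kNN-LS-SVM).

A least-squares SVM replaces the ε-insensitive loss and inequality
constraints of classic support-vector regression with equality constraints
and a squared-error penalty,

    min_{w,b,e}  ½ wᵀw + (γ/2) Σᵢ eᵢ²   s.t.  yᵢ = wᵀφ(xᵢ) + b + eᵢ,

so training reduces to one linear system in the dual variables (α, b):

    [ 0   1ᵀ ] [ b ]   [ 0 ]
    [ 1  Ω+I/γ] [ α ] = [ y ],      Ωᵢⱼ = k(xᵢ, xⱼ),

with prediction f(x) = Σᵢ αᵢ k(x, xᵢ) + b and residuals eᵢ = αᵢ/γ.

The localized variant weights the squared errors by a similarity λ(x_s, xᵢ)
to the query x_s; with the binary criterion λ = 1 iff ‖x_s − xᵢ‖ ≤ r_s
(r_s the K-th smallest distance) the weighted problem reduces to fitting an
ordinary LS-SVM on the K nearest neighbours only — one small local model per
query, which keeps per-prediction cost constant as the training pool grows
(suited to streaming / personalized prediction).  With k = N the local fit
coincides exactly with the global one.

Distances are computed on standardized features (the raw features mix BPM,
mmHg and energy scales); the Gaussian kernel k(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖²/2σ₀²)
is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_JITTER = 1e-10  # documented ridge fallback for singular dual systems


def gaussian_kernel(xi, xj, sigma0: float) -> float:
    """Gaussian similarity exp(−‖xi−xj‖² / (2σ₀²)) ∈ (0, 1]."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch {xi.shape} vs {xj.shape}")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma0**2)))


def _gram(X: np.ndarray, Z: np.ndarray, sigma0: float) -> np.ndarray:
    d2 = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma0**2))


@dataclass
class TrainingPool:
    """Instance pool with the per-feature standardization used for distances."""

    X: np.ndarray
    y: np.ndarray
    loc: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be N×d with matching y")
        if len(self.X) < 1:
            raise ValueError("pool must contain at least one instance")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("pool contains non-finite entries")
        self.loc = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)  # constant features carry no distance

    @property
    def n(self) -> int:
        return len(self.y)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.loc) / self.scale


@dataclass(frozen=True)
class Hyperparams:
    """Local-model hyperparameters.

    k is the neighbourhood size (25 for cardiology/postsurgical pools, 15 for
    the smaller dialysis pools); gamma the LS-SVM regularization constant;
    sigma0 the Gaussian kernel bandwidth (None → √d of the standardized
    feature space, a scale on which typical inter-point distances are O(√d)).
    """

    k: int = 25
    gamma: float = 10.0
    sigma0: float | None = None
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.metric not in ("euclidean", "mahalanobis", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def resolve_sigma0(self, d: int) -> float:
        return float(self.sigma0) if self.sigma0 is not None else float(np.sqrt(d))


@dataclass
class NeighborSelection:
    indices: np.ndarray   # the K selected training rows (original pool ids)
    r_s: float            # K-th smallest distance
    lam: np.ndarray       # binary weights λ(x_s, xᵢ) over the whole pool


@dataclass
class LSSVMModel:
    """Dual solution of one (local) LS-SVM fit."""

    support_X: np.ndarray
    alpha: np.ndarray
    b: float
    sigma0: float
    gamma: float

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = _gram(X, self.support_X, self.sigma0)
        return K @ self.alpha + self.b

    @property
    def residuals(self) -> np.ndarray:
        """Training errors eᵢ, recoverable from the multipliers as αᵢ/γ."""
        return self.alpha / self.gamma

    def dual_residual(self, y: np.ndarray) -> float:
        """Max-norm residual of the dual linear system at the solution."""
        Omega = _gram(self.support_X, self.support_X, self.sigma0)
        n = len(self.alpha)
        lhs_top = float(np.sum(self.alpha))
        lhs_rows = self.b + (Omega + np.eye(n) / self.gamma) @ self.alpha - y
        return max(abs(lhs_top), float(np.max(np.abs(lhs_rows))))


def fit_ls_svm(X, y, gamma: float, sigma0: float) -> LSSVMModel:
    """Solve the LS-SVM dual linear system for (b, α)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 1:
        raise ValueError("need at least one training point")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    Omega = _gram(X, X, sigma0)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = Omega + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular dual system; re-solving with ridge jitter {_JITTER}",
            stacklevel=2)
        A[1:, 1:] += _JITTER * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    return LSSVMModel(support_X=X.copy(), alpha=sol[1:], b=float(sol[0]),
                      sigma0=sigma0, gamma=gamma)


def _pool_distances(x_s, pool: TrainingPool, metric: str) -> np.ndarray:
    Xs = pool.standardize(pool.X)
    qs = pool.standardize(x_s)
    if metric == "euclidean":
        return cdist(qs, Xs, metric="euclidean")[0]
    if metric == "chebyshev":
        return cdist(qs, Xs, metric="chebyshev")[0]
    if metric == "mahalanobis":
        # shrinkage-regularized covariance of the standardized pool
        C = np.cov(Xs, rowvar=False)
        C = np.atleast_2d(C)
        lam = 0.1
        C = (1 - lam) * C + lam * np.eye(C.shape[0]) * np.trace(C) / C.shape[0]
        VI = np.linalg.inv(C)
        return cdist(qs, Xs, metric="mahalanobis", VI=VI)[0]
    raise ValueError(f"unknown metric {metric!r}")


def knn_select(x_s, pool: TrainingPool, k: int,
               metric: str = "euclidean") -> NeighborSelection:
    """Pick the K nearest pool rows by the binary similarity criterion.

    Ties at the K-th distance are broken by lowest original index, so the
    selection is invariant to pool row order (callers shuffling rows must
    carry original ids).
    """
    if not 1 <= k <= pool.n:
        raise ValueError(f"k={k} outside [1, N={pool.n}]")
    dist = _pool_distances(x_s, pool, metric)
    order = np.argsort(dist, kind="stable")  # stable → lowest index on ties
    idx = np.sort(order[:k])
    r_s = float(dist[order[k - 1]])
    lam = np.zeros(pool.n)
    lam[idx] = 1.0
    return NeighborSelection(indices=idx, r_s=r_s, lam=lam)


def predict_local(x_s, pool: TrainingPool, hp: Hyperparams) -> float:
    """kNN-LS-SVM prediction: local fit on the K nearest neighbours.

    Features are standardized (by the pool's statistics) both for the
    neighbour search and inside the kernel, so sigma0 is on the standardized
    scale.  Deterministic given pool and hyperparameters.
    """
    sel = knn_select(x_s, pool, hp.k, hp.metric)
    Xn = pool.standardize(pool.X[sel.indices])
    yn = pool.y[sel.indices]
    sigma0 = hp.resolve_sigma0(pool.X.shape[1])
    model = fit_ls_svm(Xn, yn, hp.gamma, sigma0)
    return float(model.predict(pool.standardize(x_s))[0])


def tune_hyperparameters(pool: TrainingPool, grid: dict | None = None,
                         folds: int = 5, seed: int = 0,
                         metric: str = "euclidean") -> Hyperparams:
    """Grid search minimizing cross-validated mean absolute error.

    ``grid`` maps {"k": [...], "gamma": [...], "sigma0": [...]}; defaults are
    k ∈ {5, 15, 25, 35}, γ ∈ {1, 10, 100, 1000, 10000}, σ₀ ∈
    {0.5, 1, 2, 5, 10}·√d.  Ties break toward smaller k, then smaller γ,
    then smaller σ₀.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > pool.n:
        raise ValueError("more folds than pool instances")
    d = pool.X.shape[1]
    if grid is None:
        grid = {}
    ks = grid.get("k", [5, 15, 25, 35])
    gammas = grid.get("gamma", [1.0, 10.0, 100.0, 1e3, 1e4])
    sigmas = grid.get("sigma0", [s * np.sqrt(d) for s in (0.5, 1, 2, 5, 10)])
    if not (ks and gammas and sigmas):
        raise ValueError("empty hyperparameter grid")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(pool.n)
    fold_of = np.empty(pool.n, dtype=int)
    fold_of[perm] = np.arange(pool.n) % folds

    best: tuple | None = None
    for k, gamma, sigma0 in product(ks, gammas, sigmas):
        errs = []
        for f in range(folds):
            train = fold_of != f
            if train.sum() < k:
                break
            sub = TrainingPool(pool.X[train], pool.y[train])
            hp = Hyperparams(k=k, gamma=gamma, sigma0=sigma0, metric=metric)
            for i in np.flatnonzero(~train):
                pred = predict_local(pool.X[i], sub, hp)
                errs.append(abs(pred - pool.y[i]))
        else:
            score = float(np.mean(errs))
            key = (score, k, gamma, sigma0)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no grid point admissible (k larger than every fold)")
    _, k, gamma, sigma0 = best
    return Hyperparams(k=int(k), gamma=float(gamma), sigma0=float(sigma0),
                       metric=metric)
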