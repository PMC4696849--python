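"""L1-penalized Poisson regression along a regularization path.

Fits the predictive-mean model ``E[y|x] = exp(b0 + x.b)`` by minimizing

    -(1/N) * sum_i [ y_i (b0 + x_i.b) - exp(b0 + x_i.b) ] + lambda * ||b||_1

with an unpenalized intercept, over a decreasing grid of penalty levels
(glmnet-style): outer iteratively-reweighted least squares, inner
coordinate-wise soft-thresholding on the weighted working response, warm
starts along the path. Covariates are standardized to zero mean / unit
variance internally; constant columns get coefficient zero.

A cap on model size (``max_active``) is honored by truncating the path:
the returned solution is the smallest-lambda grid point whose active-set
size is within the cap, with all larger-lambda points also within it. A
consequence is that the number of covariates actually used is typically
below the cap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "LassoFit",
    "PoissonLassoPath",
    "lambda_max",
    "fit_poisson_lasso_path",
    "fit_poisson_lasso",
    "predict_mu",
    "poisson_deviance",
]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3
CD_TOL = 1e-7
IRLS_TOL = 1e-6
CD_MAX_ITER = 10_000
IRLS_MAX_ITER = 100
ETA_CLIP = 30.0  # linear predictor clip inside IRLS, exp(30) ~ 1e13
INTERCEPT_FLOOR = float(np.log(1e-8))


@njit(cache=True)
def _cd_wls(Xs, w, r, beta, b0, lam, active_only, active, tol, max_sweeps):
    """Coordinate descent on the penalized weighted least-squares problem.

    ``r`` is the current working residual z - b0 - Xs.beta and is updated in
    place together with ``beta``; returns (b0, sweeps used, max last change).
    """
    n, p = Xs.shape
    inv_n = 1.0 / n
    sw = np.sum(w)
    denom = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * Xs[i, j] * Xs[i, j]
        denom[j] = s * inv_n
    max_delta = 0.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if active_only and not active[j]:
                continue
            if denom[j] <= 0.0:
                continue
            g = 0.0
            for i in range(n):
                g += w[i] * Xs[i, j] * r[i]
            g = g * inv_n + denom[j] * beta[j]
            if g > lam:
                bj = (g - lam) / denom[j]
            elif g < -lam:
                bj = (g + lam) / denom[j]
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * Xs[i, j]
                beta[j] = bj
                active[j] = bj != 0.0
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        # intercept (unpenalized)
        g0 = 0.0
        for i in range(n):
            g0 += w[i] * r[i]
        d0 = g0 / sw
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
        if max_delta < tol:
            return b0, sweep + 1, max_delta
    return b0, max_sweeps, max_delta


@njit(cache=True)
def _poisson_negll(y, eta):
    s = 0.0
    for i in range(y.shape[0]):
        s += np.exp(eta[i]) - y[i] * eta[i]
    return s / y.shape[0]


@njit(cache=True)
def _fit_path_kernel(Xs, y, lambdas, cd_tol, irls_tol, cd_max_iter, irls_max_iter,
                     eta_clip, b0_floor):
    """IRLS + coordinate descent over a decreasing lambda grid with warm starts."""
    n, p = Xs.shape
    L = lambdas.shape[0]
    intercepts = np.empty(L)
    betas = np.zeros((L, p))
    ybar = np.mean(y)
    b0 = np.log(ybar) if ybar > 0 else b0_floor
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    eta = np.empty(n)
    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    for li in range(L):
        lam = lambdas[li]
        obj_prev = np.inf
        for it in range(irls_max_iter):
            # working response and weights at current estimate
            for i in range(n):
                e = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        e += Xs[i, j] * beta[j]
                if e > eta_clip:
                    e = eta_clip
                elif e < -eta_clip:
                    e = -eta_clip
                eta[i] = e
                mu = np.exp(e)
                w[i] = mu
                z[i] = e + (y[i] - mu) / mu
                r[i] = z[i] - e
            budget = cd_max_iter
            # full sweep to discover the active set, then iterate on it
            b0, used, _ = _cd_wls(Xs, w, r, beta, b0, lam, False, active, cd_tol, 1)
            budget -= used
            while budget > 0:
                b0, used, _ = _cd_wls(Xs, w, r, beta, b0, lam, True, active,
                                      cd_tol, budget)
                budget -= used
                b0, used, delta = _cd_wls(Xs, w, r, beta, b0, lam, False, active,
                                          cd_tol, 1)
                budget -= used
                if delta < cd_tol:
                    break
            if b0 < b0_floor:
                b0 = b0_floor
            # penalized objective for the IRLS convergence check
            for i in range(n):
                e = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        e += Xs[i, j] * beta[j]
                if e > eta_clip:
                    e = eta_clip
                elif e < -eta_clip:
                    e = -eta_clip
                eta[i] = e
            obj = _poisson_negll(y, eta)
            for j in range(p):
                obj += lam * abs(beta[j])
            if abs(obj_prev - obj) < irls_tol * (abs(obj) + 1.0):
                break
            obj_prev = obj
        intercepts[li] = b0
        betas[li] = beta
    return intercepts, betas


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal.

    Computed on the standardized design: ``max_j |(1/N) sum_i x_ij (y_i - ybar)|``.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))


def default_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = N_LAMBDA,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:  # degenerate outcome (e.g. all equal): any penalty nulls the fit
        lmax = 1.0
    return np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)


@dataclass(frozen=True)
class LassoFit:
    """A fitted penalized Poisson mean model at one penalty level.

    Coefficients are on the standardized scale; ``standardization`` holds
    the per-covariate (mean, scale) applied before fitting so new data can
    be mapped into the same space.
    """

    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    lambda_: float
    standardization: tuple[np.ndarray, np.ndarray]
    max_active: int | None = None

    @property
    def active_set(self) -> list[str]:
        return [self.feature_names[j] for j in np.flatnonzero(self.coefficients)]

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def to_json(self) -> str:
        means, scales = self.standardization
        return json.dumps(
            {
                "intercept": self.intercept,
                "lambda": self.lambda_,
                "max_active": self.max_active,
                "coefficients": dict(
                    zip(self.feature_names, (float(b) for b in self.coefficients))
                ),
                "standardization": {
                    name: {"mean": float(m), "scale": float(s)}
                    for name, m, s in zip(self.feature_names, means, scales)
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LassoFit":
        d = json.loads(text)
        names = list(d["coefficients"])
        return cls(
            intercept=d["intercept"],
            coefficients=np.array([d["coefficients"][n] for n in names]),
            feature_names=names,
            lambda_=d["lambda"],
            standardization=(
                np.array([d["standardization"][n]["mean"] for n in names]),
                np.array([d["standardization"][n]["scale"] for n in names]),
            ),
            max_active=d["max_active"],
        )


@dataclass
class PoissonLassoPath:
    """Solutions over a decreasing penalty grid (shared standardization)."""

    lambdas: np.ndarray
    intercepts: np.ndarray
    coefficients: np.ndarray  # (L, p), standardized scale
    feature_names: list[str]
    standardization: tuple[np.ndarray, np.ndarray]
    n_active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n_active = np.count_nonzero(self.coefficients, axis=1)

    def solution(self, index: int, max_active: int | None = None) -> LassoFit:
        return LassoFit(
            intercept=float(self.intercepts[index]),
            coefficients=self.coefficients[index].copy(),
            feature_names=self.feature_names,
            lambda_=float(self.lambdas[index]),
            standardization=self.standardization,
            max_active=max_active,
        )

    def truncation_index(self, max_active: int) -> int:
        """Last grid index of the prefix whose active sizes all fit the cap."""
        ok = self.n_active <= max_active
        if not ok[0]:
            return 0  # null end of the path always satisfies any cap >= 0
        bad = np.flatnonzero(~ok)
        return int(bad[0] - 1) if bad.size else len(self.lambdas) - 1


def fit_poisson_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> PoissonLassoPath:
    """Fit the full regularization path (decreasing lambda, warm starts)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with rows matching y")
    if np.isnan(X).any():
        raise ValueError("X must have no missing entries")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if y.max() == 0:
        warnings.warn(
            "all outcomes are zero; intercept clamped at log(1e-8)", stacklevel=2
        )
    if lambdas is None:
        lambdas = default_lambda_grid(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be non-increasing")
    Xs, means, scales = _standardize(X)
    intercepts, betas = _fit_path_kernel(
        np.ascontiguousarray(Xs), y, lambdas,
        CD_TOL, IRLS_TOL, CD_MAX_ITER, IRLS_MAX_ITER, ETA_CLIP, INTERCEPT_FLOOR,
    )
    return PoissonLassoPath(
        lambdas=lambdas,
        intercepts=intercepts,
        coefficients=betas,
        feature_names=list(feature_names),
        standardization=(means, scales),
    )


def fit_poisson_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float | None = None,
    max_active: int | None = None,
    feature_names: list[str] | None = None,
) -> LassoFit:
    """Fit at one penalty level, optionally under an active-set cap.

    When ``lambda_`` is given, the path is run from ``lambda_max`` down to
    it (warm starts stabilize the solution) and the endpoint returned;
    ``lambda_ = 0`` appends an unpenalized endpoint. When only
    ``max_active`` is given, the default grid is fitted and truncated per
    the cap. With neither, the smallest grid penalty is returned (use
    cross-validation to pick a penalty in practice; see
    :mod:`fallforecast.cv`).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_active is not None and max_active < 0:
        raise ValueError("max_active must be non-negative")
    lmax = lambda_max(X, y)
    if lambda_ is not None and lambda_ >= lmax > 0:
        grid = np.array([lambda_])
    elif lambda_ is not None:
        base = default_lambda_grid(X, y)
        grid = np.append(base[base > lambda_], lambda_)
    else:
        grid = default_lambda_grid(X, y)
    path = fit_poisson_lasso_path(X, y, lambdas=grid, feature_names=feature_names)
    idx = len(grid) - 1
    if max_active is not None:
        idx = min(idx, path.truncation_index(max_active))
    return path.solution(idx, max_active=max_active)


def predict_mu(fit: LassoFit, X_new: np.ndarray) -> np.ndarray:
    """Predictive means ``exp(b0 + x_std . beta)`` for new design rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(fit.feature_names):
        raise ValueError(
            f"X_new must have {len(fit.feature_names)} columns "
            f"({', '.join(fit.feature_names[:5])}...)"
        )
    means, scales = fit.standardization
    eta = fit.intercept + ((X_new - means) / scales) @ fit.coefficients
    return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Mean Poisson deviance, used to select the penalty by cross-validation."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.mean(term - (y - mu)))
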