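"""Negative-binomial predictive distributions and dispersion estimation.

The forecast for a sample is a negative binomial (NB2) distribution over
future fall counts, parameterized by mean ``mu`` and dispersion ``theta``
with variance ``mu + mu**2 / theta``; as ``theta`` grows the distribution
approaches a Poisson with the same mean. The mean comes from a penalized
Poisson regression (:mod:`fallforecast.lasso`); ``theta`` is a single
maximum-likelihood estimate over all training samples given their fitted
means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["NBPrediction", "ThetaEstimate", "nb_pmf", "nb_cdf", "nb_loglik", "estimate_theta"]

MU_FLOOR = 1e-8
THETA_BOUNDS = (1e-3, 1e6)


@dataclass(frozen=True)
class NBPrediction:
    """A predictive NB distribution: mean ``mu`` >= 0, dispersion ``theta`` > 0.

    ``mu`` may be a scalar or an array (one predictive distribution per
    sample, sharing the dispersion).
    """

    mu: float | np.ndarray
    theta: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if np.any(np.asarray(self.mu) < 0):
            raise ValueError("mu must be non-negative")

    def _frozen(self, mu=None) -> stats.rv_discrete:
        m = np.maximum(self.mu if mu is None else mu, MU_FLOOR)
        return stats.nbinom(self.theta, self.theta / (self.theta + m))

    def pmf(self, y) -> np.ndarray | float:
        return nb_pmf(self, y)

    def cdf(self, y) -> np.ndarray | float:
        return nb_cdf(self, y)

    def mean(self):
        return self.mu

    def var(self):
        return np.asarray(self.mu) + np.asarray(self.mu) ** 2 / self.theta


def nb_pmf(pred: NBPrediction, y) -> np.ndarray | float:
    """P(Y = y) under the predictive distribution.

    Equals ``Gamma(y+theta) / (Gamma(theta) y!) * (theta/(theta+mu))**theta
    * (mu/(theta+mu))**y``; evaluated in log space via scipy. An exact-zero
    mean degenerates to a point mass at zero.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or np.any(y_arr != np.round(y_arr)):
        raise ValueError("y must be a non-negative integer")
    out = pred._frozen().pmf(y_arr)
    mu_arr = np.asarray(pred.mu)
    if np.any(mu_arr == 0):  # exact degenerate case, not the floored one
        zero = np.broadcast_to(mu_arr == 0, np.broadcast_shapes(mu_arr.shape, y_arr.shape))
        out = np.where(zero, (y_arr == 0).astype(float), out)
    return float(out) if np.isscalar(y) and np.isscalar(pred.mu) else out


def nb_cdf(pred: NBPrediction, y) -> np.ndarray | float:
    """P(Y <= y); 0 for y < 0, nondecreasing, -> 1 as y -> inf."""
    y_arr = np.floor(np.asarray(y, dtype=float))
    out = np.where(y_arr < 0, 0.0, pred._frozen().cdf(np.maximum(y_arr, 0)))
    mu_arr = np.asarray(pred.mu)
    if np.any(mu_arr == 0):
        zero = np.broadcast_to(mu_arr == 0, out.shape)
        out = np.where(zero & (y_arr >= 0), 1.0, out)
    return float(out) if np.isscalar(y) and np.isscalar(pred.mu) else out


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Total NB log-likelihood of counts ``y`` given per-sample means ``mu``."""
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    return float(np.sum(stats.nbinom.logpmf(y, theta, theta / (theta + mu))))


@dataclass(frozen=True)
class ThetaEstimate:
    """MLE of the NB dispersion given fixed means.

    ``at_upper_bound`` flags the Poisson-like regime where the data show no
    overdispersion relative to the supplied means and the likelihood is
    maximized at (or beyond) the upper bound.
    """

    theta: float
    at_upper_bound: bool
    loglik: float

    def __float__(self) -> float:
        return self.theta


def estimate_theta(
    y: np.ndarray,
    mu: np.ndarray,
    theta_bounds: tuple[float, float] = THETA_BOUNDS,
) -> ThetaEstimate:
    """Maximum-likelihood NB dispersion for observed counts with fixed means.

    Maximizes ``sum_i log NB(y_i; mu_i, theta)`` over ``log theta`` in
    ``theta_bounds`` (1-D bounded optimization). Means are clamped at
    ``1e-8``. When the likelihood is maximized at the upper bound — e.g.
    equidispersed or underdispersed counts — the bound itself is returned
    with ``at_upper_bound=True``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    if y.size == 0:
        raise ValueError("empty inputs")
    if y.shape != mu.shape:
        raise ValueError(f"length mismatch: y has {y.shape}, mu has {mu.shape}")
    lo, hi = theta_bounds
    if not (0 < lo < hi):
        raise ValueError("theta_bounds must be a positive increasing interval")

    def negll(log_theta: float) -> float:
        return -nb_loglik(y, mu, float(np.exp(log_theta)))

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    ll_hat = -float(res.fun)
    ll_hi = nb_loglik(y, mu, hi)
    # bounded Brent can stall just inside the bracket when the optimum is at
    # the boundary; prefer the bound whenever it is at least as likely
    if ll_hi >= ll_hat - 1e-10 or theta >= 0.99 * hi:
        return ThetaEstimate(theta=hi, at_upper_bound=True, loglik=ll_hi)
    ll_lo = nb_loglik(y, mu, lo)
    if ll_lo >= ll_hat - 1e-10:
        return ThetaEstimate(theta=lo, at_upper_bound=False, loglik=ll_lo)
    return ThetaEstimate(theta=theta, at_upper_bound=False, loglik=ll_hat)
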