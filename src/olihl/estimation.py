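"""Estimators of the OLiHL shape parameter from a complete sample.

Four methods are provided:

* MLE — the score equation n(2+lam)/(lam(1+lam)) = S with S = (1/2) sum(e^x - 1)
  rearranges to the quadratic S lam^2 + (S - n) lam - 2n = 0, whose unique
  positive root gives the maximum-likelihood estimate in closed form.  The
  standard error comes from the analytic observed information
  -l''(lam) = 2n/lam^2 - n/(1+lam)^2.
* LSE / WLSE — least squares of the fitted cdf against the uniform order
  statistic means j/(n+1), the WLSE weighting each term by the reciprocal
  order-statistic variance (n+1)^2 (n+2) / (j (n-j+1)).
* CVME — the Cramer-von Mises minimum-distance criterion
  1/(12n) + sum [F(x_(j)) - (2j-1)/(2n)]^2.

The minimum-distance objectives are smooth in lambda but can be flat; they are
minimized on a log-lambda grid over [1e-6, 1e3] followed by local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .distribution import OLiHL, LifetimeSample

__all__ = [
    "FitResult",
    "OLiHLEstimator",
    "log_likelihood",
    "fit_mle",
    "fit_lse",
    "fit_wlse",
    "fit_cvme",
]

_METHODS = ("mle", "lse", "wlse", "cvme")
_LAMBDA_BOUNDS = (1e-6, 1e3)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a univariate OLiHL fit."""

    lambda_hat: float
    method: str
    objective_value: float
    n_obs: int
    converged: bool = True
    se: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    ci_level: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lambda_hat <= 0:
            raise ValueError("lambda_hat must be positive")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo < self.lambda_hat < hi):
                raise ValueError("confidence interval must bracket the estimate")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")

    def to_dict(self) -> dict:
        d = {
            "lambda_hat": self.lambda_hat,
            "method": self.method,
            "objective_value": self.objective_value,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "se": self.se,
            "ci_level": self.ci_level,
        }
        d["ci"] = list(self.ci) if self.ci is not None else None
        return d


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, LifetimeSample):
        return sample.values
    return LifetimeSample(np.asarray(sample, dtype=float)).values


def log_likelihood(sample, lam: float) -> float:
    """Log-likelihood of a complete OLiHL sample,

    l(lam) = 2n ln lam - n ln(4 + 4 lam) + sum ln(1 + e^x)
             - (lam/2) sum(e^x - 1) + sum x.
    """
    x = _as_values(sample)
    n = x.size
    if np.any(x > 709.0):
        raise OverflowError("e^x overflows double precision for some observation")
    return float(
        2.0 * n * np.log(lam)
        - n * np.log(4.0 + 4.0 * lam)
        + np.sum(np.logaddexp(0.0, x))
        - 0.5 * lam * np.sum(np.expm1(x))
        + np.sum(x)
    )


def _mle_closed_form(x: np.ndarray) -> float:
    n = x.size
    S = 0.5 * np.sum(np.expm1(x))
    assert S > 0.0  # impossible to violate for positive lifetimes
    return float(((n - S) + np.sqrt((n - S) ** 2 + 8.0 * n * S)) / (2.0 * S))


def _mle_se(lam: float, n: int) -> float:
    """SE from the analytic observed information -l''(lam) = 2n/lam^2 - n/(1+lam)^2."""
    info = 2.0 * n / lam**2 - n / (1.0 + lam) ** 2
    return float(info**-0.5)


def _distance_objective(method: str, x_sorted: np.ndarray):
    n = x_sorted.size
    j = np.arange(1, n + 1)
    if method == "lse":
        pp, w, const = j / (n + 1.0), 1.0, 0.0
    elif method == "wlse":
        pp = j / (n + 1.0)
        w = (n + 1.0) ** 2 * (n + 2.0) / (j * (n - j + 1.0))
        const = 0.0
    elif method == "cvme":
        pp, w, const = (2.0 * j - 1.0) / (2.0 * n), 1.0, 1.0 / (12.0 * n)
    else:  # pragma: no cover
        raise ValueError(method)

    def obj(lam: float) -> float:
        u = OLiHL(lam).cdf(x_sorted)
        return float(const + np.sum(w * (u - pp) ** 2))

    return obj


def _minimize_scalar_logspace(obj) -> Tuple[float, float, bool]:
    """Coarse log-lambda grid scan followed by bounded local refinement."""
    lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, 400)
    vals = np.array([obj(np.exp(t)) for t in grid])
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: obj(np.exp(t)), bounds=(a, b), method="bounded",
        options={"xatol": 1e-12},
    )
    lam, val = float(np.exp(res.x)), float(res.fun)
    if val > vals[k]:  # refinement should never lose to the grid
        lam, val = float(np.exp(grid[k])), float(vals[k])
    return lam, val, bool(res.success)


def fit_mle(sample, ci_level: float = 0.95) -> FitResult:
    """Closed-form maximum-likelihood fit with Wald interval."""
    x = _as_values(sample)
    if np.any(x > 709.0):
        raise OverflowError("e^x overflows double precision for some observation")
    lam = _mle_closed_form(x)
    se = _mle_se(lam, x.size)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return FitResult(
        lambda_hat=lam,
        method="mle",
        objective_value=log_likelihood(x, lam),
        n_obs=x.size,
        se=se,
        ci=(lam - z * se, lam + z * se),
        ci_level=ci_level,
    )


def _fit_distance(sample, method: str) -> FitResult:
    x = np.sort(_as_values(sample))
    obj = _distance_objective(method, x)
    lam, val, ok = _minimize_scalar_logspace(obj)
    return FitResult(
        lambda_hat=lam, method=method, objective_value=val,
        n_obs=x.size, converged=ok,
    )


def fit_lse(sample) -> FitResult:
    """Least-squares fit against plotting positions j/(n+1)."""
    return _fit_distance(sample, "lse")


def fit_wlse(sample) -> FitResult:
    """Weighted least-squares fit (inverse order-statistic variances)."""
    return _fit_distance(sample, "wlse")


def fit_cvme(sample) -> FitResult:
    """Cramer-von Mises minimum-distance fit."""
    return _fit_distance(sample, "cvme")


_FITTERS = {"mle": fit_mle, "lse": fit_lse, "wlse": fit_wlse, "cvme": fit_cvme}


class OLiHLEstimator(BaseEstimator):
    """Scikit-learn style estimator of the OLiHL shape parameter.

    Parameters
    ----------
    method : {"mle", "lse", "wlse", "cvme"}, default="mle"
        Estimation principle: closed-form maximum likelihood, (weighted)
        least squares on plotting positions, or Cramer-von Mises distance.
    ci_level : float, default=0.95
        Level of the Wald interval (MLE only).

    Attributes
    ----------
    lambda_ : float
        Estimated shape parameter.
    se_ : float or None
        Asymptotic standard error (MLE only).
    ci_ : tuple of float or None
        Wald confidence interval (MLE only).
    objective_value_ : float
        Maximized log-likelihood or minimized distance.
    result_ : FitResult
        Full fit record.
    """

    def __init__(self, method: str = "mle", ci_level: float = 0.95):
        self.method = method
        self.ci_level = ci_level

    def fit(self, X, y=None):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        x = np.asarray(X, dtype=float).ravel()
        if self.method == "mle":
            res = fit_mle(x, ci_level=self.ci_level)
        else:
            res = _FITTERS[self.method](x)
        self.result_ = res
        self.lambda_ = res.lambda_hat
        self.se_ = res.se
        self.ci_ = res.ci
        self.objective_value_ = res.objective_value
        self.n_obs_ = res.n_obs
        self.converged_ = res.converged
        return self

    def score(self, X, y=None) -> float:
        """Mean log-likelihood of X under the fitted shape parameter."""
        x = np.asarray(X, dtype=float).ravel()
        return log_likelihood(x, self.lambda_) / x.size

    @property
    def distribution_(self) -> OLiHL:
        return OLiHL(self.lambda_)
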