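"""Censored log-location-scale (AFT-type) regression with LOLiHL errors.

If X follows the OLiHL law, Y = log X follows the log-OLiHL (LOLiHL)
distribution; adding location and scale gives the three-parameter family
with standardized residual z = (y - mu)/sigma and w = e^z:

    log f(y) = 2 ln lambda - ln(4 sigma (lambda+1)) + ln(1 + e^w) + z + w
               - (lambda/2)(e^w - 1),
    log S(y) = ln(lambda e^w... ) -- precisely
               ln(lambda + lambda e^w + 2) - ln(2 lambda + 2)
               - (lambda/2)(e^w - 1).

The survival exponent is (e^w - 1): the alternative "+1" sign that sometimes
appears in print fails the boundary requirement S(-inf) = 1 and disagrees
with the OLiHL survival function under the change of variables; it remains
available via ``convention="printed"`` for forensic comparison.

The regression links covariates to the location, mu_i = x_i' beta, and
maximizes the right-censored likelihood

    l(theta) = sum_{events} log f(y_i) + sum_{censored} log S(y_i)

over theta = (lambda, beta, sigma) in the unconstrained parametrization
(ln lambda, beta, ln sigma).  Standard errors come from the numerically
differentiated observed information mapped back to the natural scale by the
delta method; Wald z and two-sided normal p-values are reported for each
coefficient.  Martingale and modified deviance residuals follow the
standard censored-data definitions with the LOLiHL survival function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "LOLiHLParams",
    "SurvivalDataset",
    "RegressionFit",
    "LOLiHLRegressor",
    "lolihl_logpdf",
    "lolihl_logsf",
    "censored_loglik",
    "fit_regression",
    "residuals",
]

_W_OVERFLOW = 709.0  # expm1(w) overflows beyond this


@dataclass(frozen=True)
class LOLiHLParams:
    """Shape, location and scale of the LOLiHL distribution."""

    lam: float
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError("lambda must be a finite positive real")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be a finite positive real")


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored log-lifetimes with a covariate matrix.

    ``y`` holds min(log lifetime, log censoring time); ``delta`` is 1 for an
    observed event and 0 for a censored record; ``X`` includes a leading
    intercept column.
    """

    y: np.ndarray
    delta: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        delta = np.asarray(self.delta).ravel()
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not (y.size == delta.size == X.shape[0]):
            raise ValueError("y, delta and X row counts disagree")
        if not np.all(np.isin(delta, (0, 1))):
            raise ValueError("delta must contain only 0 (censored) and 1 (event)")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("y and X must be finite")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            import warnings

            warnings.warn("covariate matrix is rank deficient", stacklevel=2)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "delta", delta.astype(int))
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def k(self) -> int:
        """Number of covariate columns (including the intercept)."""
        return int(self.X.shape[1])

    @property
    def n_events(self) -> int:
        return int(np.sum(self.delta))


def _z_w(y, p: LOLiHLParams):
    z = (np.asarray(y, dtype=float) - p.mu) / p.sigma
    w = np.exp(np.minimum(z, _W_OVERFLOW))
    return z, w


def _check_w(w) -> None:
    if np.any(w > _W_OVERFLOW):
        idx = np.flatnonzero(np.atleast_1d(w) > _W_OVERFLOW)
        raise OverflowError(
            f"exp(exp(z)) overflows double precision at index {idx[0]}"
        )


def lolihl_logpdf(y, p: LOLiHLParams):
    """Log-density of the LOLiHL distribution."""
    z, w = _z_w(y, p)
    _check_w(w)
    return (
        2.0 * np.log(p.lam)
        - np.log(4.0 * p.sigma * (p.lam + 1.0))
        + np.logaddexp(0.0, w)
        + z
        + w
        - 0.5 * p.lam * np.expm1(w)
    )


def lolihl_logsf(y, p: LOLiHLParams, convention: str = "corrected"):
    """Log-survival of the LOLiHL distribution.

    ``convention="corrected"`` (default) uses the (e^w - 1) exponent that
    satisfies S(-inf) = 1; ``"printed"`` uses the (e^w + 1) variant for
    forensic comparison only.
    """
    if convention not in ("corrected", "printed"):
        raise ValueError("convention must be 'corrected' or 'printed'")
    z, w = _z_w(y, p)
    _check_w(w)
    tail = np.expm1(w) if convention == "corrected" else np.exp(w) + 1.0
    return (
        np.logaddexp(np.log(p.lam) + w, np.log(p.lam + 2.0))
        - np.log(2.0 * p.lam + 2.0)
        - 0.5 * p.lam * tail
    )


def lolihl_sf(y, p: LOLiHLParams, convention: str = "corrected"):
    return np.exp(lolihl_logsf(y, p, convention))


def lolihl_cdf(y, p: LOLiHLParams):
    return -np.expm1(lolihl_logsf(y, p))


def censored_loglik(data: SurvivalDataset, lam: float, beta, sigma: float,
                    convention: str = "corrected") -> float:
    """Right-censored log-likelihood: event rows contribute log f, censored
    rows log S, with location mu_i = x_i' beta."""
    beta = np.asarray(beta, dtype=float)
    mu = data.X @ beta
    z = (data.y - mu) / sigma
    w = np.exp(np.minimum(z, _W_OVERFLOW))
    if np.any(w > _W_OVERFLOW):
        idx = int(np.flatnonzero(w > _W_OVERFLOW)[0])
        raise OverflowError(f"exp(exp(z)) overflows at row {idx}")
    tail = np.expm1(w) if convention == "corrected" else np.exp(w) + 1.0
    logf = (
        2.0 * np.log(lam)
        - np.log(4.0 * sigma * (lam + 1.0))
        + np.logaddexp(0.0, w)
        + z
        + w
        - 0.5 * lam * np.expm1(w)
    )
    logS = (
        np.logaddexp(np.log(lam) + w, np.log(lam + 2.0))
        - np.log(2.0 * lam + 2.0)
        - 0.5 * lam * tail
    )
    ev = data.delta == 1
    return float(np.sum(logf[ev]) + np.sum(logS[~ev]))


@dataclass
class RegressionFit:
    """Fitted LOLiHL regression: theta = (lambda, beta, sigma) with Wald table."""

    lam: float
    beta: np.ndarray
    sigma: float
    se: Optional[np.ndarray]  # order (lambda, beta..., sigma); None if singular
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_events: int
    martingale: np.ndarray = field(default=None, repr=False)
    deviance: np.ndarray = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return 2 + self.beta.size

    @property
    def z_stat(self) -> Optional[np.ndarray]:
        if self.se is None:
            return None
        return self.beta / self.se[1:-1]

    @property
    def p_values(self) -> Optional[np.ndarray]:
        z = self.z_stat
        if z is None:
            return None
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        se = None if self.se is None else self.se.tolist()
        pv = self.p_values
        return {
            "lambda": self.lam,
            "beta": self.beta.tolist(),
            "sigma": self.sigma,
            "se": se,
            "z_stat": None if self.z_stat is None else self.z_stat.tolist(),
            "p_values": None if pv is None else pv.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }


def _pack(lam, beta, sigma):
    return np.concatenate([[np.log(lam)], np.ravel(beta), [np.log(sigma)]])


def _unpack(theta):
    return float(np.exp(theta[0])), np.asarray(theta[1:-1]), float(np.exp(theta[-1]))


def _numeric_hessian(fun, theta):
    p = theta.size
    H = np.empty((p, p))
    h = 1e-5 * (1.0 + np.abs(theta))
    f0 = fun(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H, f0


def residuals(data: SurvivalDataset, lam: float, beta, sigma: float,
              convention: str = "corrected") -> dict:
    """Martingale and modified deviance residuals at the given parameters.

    r_M = delta + log S(y); events give r_M in (-inf, 1], censored rows
    r_M <= 0.  The deviance transform is
    sign(r_M) sqrt(-2 [r_M + log(1 - r_M)]) for events and
    sign(r_M) sqrt(-2 r_M) for censored rows; an event with r_M exactly 1
    yields an infinite deviance residual, flagged by a warning.
    """
    mu = data.X @ np.asarray(beta, dtype=float)
    logS = np.array([
        float(lolihl_logsf(yi, LOLiHLParams(lam, mi, sigma), convention))
        for yi, mi in zip(data.y, mu)
    ])
    rM = data.delta + logS
    ev = data.delta == 1
    rD = np.empty_like(rM)
    with np.errstate(divide="ignore", invalid="ignore"):
        rD[ev] = np.sign(rM[ev]) * np.sqrt(-2.0 * (rM[ev] + np.log1p(-rM[ev])))
        rD[~ev] = np.sign(rM[~ev]) * np.sqrt(-2.0 * rM[~ev])
    if np.any(~np.isfinite(rD)):
        import warnings

        warnings.warn("infinite deviance residual (martingale residual at 1)",
                      stacklevel=2)
    return {"martingale": rM, "deviance": rD}


def fit_regression(data: SurvivalDataset, convention: str = "corrected",
                   lambda_starts: Sequence[float] = (0.5, 5.0, 20.0)) -> RegressionFit:
    """Maximum-likelihood fit of the LOLiHL regression.

    Quasi-Newton minimization of the negative censored log-likelihood over
    (ln lambda, beta, ln sigma), multi-started over ``lambda_starts`` with
    beta initialized by least squares of y on X and sigma by the residual
    standard deviation.  The flat-in-lambda likelihood surface this family
    can produce makes the multi-start essential.
    """
    n, k = data.n, data.k
    if n <= k + 2:
        raise ValueError("need n > number of parameters")

    beta0, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    resid = data.y - data.X @ beta0
    sigma0 = max(float(np.std(resid)), 1e-3)

    def nll(theta):
        lam, beta, sigma = _unpack(theta)
        try:
            return -censored_loglik(data, lam, beta, sigma, convention)
        except (OverflowError, FloatingPointError):
            return np.inf

    best = None
    for lam0 in lambda_starts:
        x0 = _pack(lam0, beta0, sigma0)
        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    # BFGS can stop on precision loss at the optimum; a simplex polish both
    # verifies and (rarely) improves the point
    polish = optimize.minimize(nll, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 5000})
    converged = bool(best.success or polish.success)
    if polish.fun <= best.fun:
        best = polish
    theta = best.x
    lam, beta, sigma = _unpack(theta)

    H, f0 = _numeric_hessian(nll, theta)
    se = None
    try:
        cov_t = np.linalg.inv(H)
        # delta method back to the natural scale for lambda and sigma
        J = np.ones(theta.size)
        J[0], J[-1] = lam, sigma
        var = np.diag(cov_t) * J**2
        if np.all(var > 0):
            se = np.sqrt(var)
        else:
            import warnings

            warnings.warn("observed information not positive definite; no SEs",
                          stacklevel=2)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular observed information; no SEs", stacklevel=2)

    loglik = -float(best.fun)
    n_par = k + 2
    res_d = residuals(data, lam, beta, sigma, convention)
    return RegressionFit(
        lam=lam, beta=beta, sigma=sigma, se=se, loglik=loglik,
        aic=2.0 * n_par - 2.0 * loglik, converged=converged,
        n_obs=n, n_events=data.n_events,
        martingale=res_d["martingale"], deviance=res_d["deviance"],
    )


class LOLiHLRegressor(BaseEstimator):
    """Scikit-learn style censored AFT regressor with LOLiHL errors.

    Parameters
    ----------
    fit_intercept : bool, default=True
        Prepend an intercept column to X.
    log_time : bool, default=False
        If True, ``y`` passed to :meth:`fit` is a raw lifetime and is
        log-transformed internally (it must then be positive).
    convention : {"corrected", "printed"}, default="corrected"
        Sign convention of the survival exponent; see module docstring.

    Attributes
    ----------
    lambda_, sigma_ : float
        Fitted shape and scale.
    coef_ : ndarray of shape (k,)
        Covariate coefficients (excluding the intercept).
    intercept_ : float
    se_ : ndarray or None
        Standard errors in the order (lambda, intercept, coef..., sigma).
    loglik_, aic_ : float
    result_ : RegressionFit
    """

    def __init__(self, fit_intercept: bool = True, log_time: bool = False,
                 convention: str = "corrected"):
        self.fit_intercept = fit_intercept
        self.log_time = log_time
        self.convention = convention

    def _dataset(self, X, y, event) -> SurvivalDataset:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if self.log_time:
            if np.any(y <= 0):
                raise ValueError("lifetimes must be positive for log_time=True")
            y = np.log(y)
        if event is None:
            event = np.ones_like(y, dtype=int)
        if self.fit_intercept:
            X = np.column_stack([np.ones(y.size), X])
        return SurvivalDataset(y=y, delta=np.asarray(event), X=X)

    def fit(self, X, y, event=None):
        data = self._dataset(X, y, event)
        res = fit_regression(data, convention=self.convention)
        self.result_ = res
        self.lambda_ = res.lam
        self.sigma_ = res.sigma
        if self.fit_intercept:
            self.intercept_ = float(res.beta[0])
            self.coef_ = res.beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = res.beta.copy()
        self.se_ = res.se
        self.loglik_ = res.loglik
        self.aic_ = res.aic
        self.n_features_in_ = self.coef_.size
        return self

    def predict(self, X):
        """Location (expected log-lifetime up to the error mean) mu = X beta."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_

    def predict_survival(self, X, times):
        """Survival probabilities S(log t | x) on the lifetime scale."""
        mu = np.atleast_1d(self.predict(X))
        times = np.asarray(times, dtype=float)
        if np.any(times <= 0):
            raise ValueError("times must be positive")
        out = np.empty((mu.size, times.size))
        for i, m in enumerate(mu):
            out[i] = lolihl_sf(np.log(times),
                               LOLiHLParams(self.lambda_, m, self.sigma_),
                               self.convention)
        return out

    def score(self, X, y, event=None) -> float:
        """Mean censored log-likelihood under the fitted parameters."""
        data = self._dataset(X, y, event)
        beta = (np.concatenate([[self.intercept_], self.coef_])
                if self.fit_intercept else self.coef_)
        return censored_loglik(data, self.lambda_, beta, self.sigma_,
                               self.convention) / data.n

    def residuals_(self, X, y, event=None) -> dict:
        data = self._dataset(X, y, event)
        beta = (np.concatenate([[self.intercept_], self.coef_])
                if self.fit_intercept else self.coef_)
        return residuals(data, self.lambda_, beta, self.sigma_, self.convention)
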