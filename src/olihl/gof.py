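"""Goodness-of-fit machinery and one-parameter competitor models.

Seven one-parameter lifetime laws are compared on a common panel of
statistics: negative maximized log-likelihood, AIC, the Anderson-Darling
(A*) and Cramer-von Mises (W*) EDF statistics with the standard
Chen-Balakrishnan small-sample modification factors, and the
Kolmogorov-Smirnov statistic with its asymptotic p-value.  The competitors
are the classical generalizations of the half-logistic (HL) law —
exponentiated HL, generalized HL, transmuted HL — plus the Lindley, inverse
Lindley and exponential distributions.

Only cdfs are specified for the competitors in the source literature; the
densities here are their analytic derivatives (each is verified numerically
in the test suite).  The scaled total-time-on-test (TTT) transform is
provided as an empirical diagnostic for increasing hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .distribution import OLiHL, LifetimeSample
from .estimation import fit_mle, _as_values

__all__ = [
    "CompetitorModel",
    "CompetitorFit",
    "GofReport",
    "MODELS",
    "get_model",
    "fit_competitor",
    "ks_test",
    "edf_statistics",
    "ttt_transform",
    "pp_points",
    "compare_models",
]


# ---------------------------------------------------------------------------
# model definitions

def _hl_cdf(x):
    # half-logistic baseline G(x) = (1 - e^-x) / (1 + e^-x)
    return -np.expm1(-x) / (1.0 + np.exp(-x))


def _hl_logpdf(x):
    # g(x) = 2 e^-x / (1 + e^-x)^2
    return np.log(2.0) - x - 2.0 * np.logaddexp(0.0, -x)


def _ehl_cdf(x, lam):
    return _hl_cdf(x) ** lam


def _ehl_logpdf(x, lam):
    return np.log(lam) + (lam - 1.0) * np.log(_hl_cdf(x)) + _hl_logpdf(x)


def _ghl_cdf(x, lam):
    # survival (2 e^-x / (1 + e^-x))^lam = (2/(e^x+1))^lam
    return -np.expm1(lam * (np.log(2.0) - np.logaddexp(0.0, x)))


def _ghl_logpdf(x, lam):
    return np.log(lam) + (lam - 1.0) * (np.log(2.0) - np.logaddexp(0.0, x)) + _hl_logpdf(x)


def _lindley_cdf(x, lam):
    return -np.expm1(-lam * x + np.log1p(lam * x / (1.0 + lam)))


def _lindley_logpdf(x, lam):
    return 2.0 * np.log(lam) - np.log1p(lam) + np.log1p(x) - lam * x


def _ilindley_cdf(x, lam):
    # inverse Lindley: F(x) = (1 + lam / ((1+lam) x)) e^{-lam/x}
    return (1.0 + lam / ((1.0 + lam) * x)) * np.exp(-lam / x)


def _ilindley_logpdf(x, lam):
    return (
        2.0 * np.log(lam) - np.log1p(lam) + np.log1p(x) - 3.0 * np.log(x) - lam / x
    )


def _thl_cdf(x, lam):
    # transmuted HL: (1+lam) G - lam G^2 with the HL baseline, |lam| < 1
    G = _hl_cdf(x)
    return (1.0 + lam) * G - lam * G**2


def _thl_logpdf(x, lam):
    G = _hl_cdf(x)
    return _hl_logpdf(x) + np.log(1.0 + lam - 2.0 * lam * G)


def _exp_cdf(x, lam):
    return -np.expm1(-lam * x)


def _exp_logpdf(x, lam):
    return np.log(lam) - lam * x


def _olihl_cdf(x, lam):
    return OLiHL(lam).cdf(x)


def _olihl_logpdf(x, lam):
    return OLiHL(lam).logpdf(x)


@dataclass(frozen=True)
class CompetitorModel:
    """A one-parameter lifetime model entering the comparison."""

    name: str
    cdf: Callable[[np.ndarray, float], np.ndarray]
    logpdf: Callable[[np.ndarray, float], np.ndarray]
    param_domain: Tuple[float, float] = (1e-6, 1e3)
    log_param: bool = True  # optimize on the log scale (positive domains)

    def pdf(self, x, lam):
        return np.exp(self.logpdf(np.asarray(x, float), lam))


MODELS: Dict[str, CompetitorModel] = {
    "olihl": CompetitorModel("olihl", _olihl_cdf, _olihl_logpdf),
    "ehl": CompetitorModel("ehl", _ehl_cdf, _ehl_logpdf),
    "ghl": CompetitorModel("ghl", _ghl_cdf, _ghl_logpdf),
    "li": CompetitorModel("li", _lindley_cdf, _lindley_logpdf),
    "ili": CompetitorModel("ili", _ilindley_cdf, _ilindley_logpdf),
    "thl": CompetitorModel(
        "thl", _thl_cdf, _thl_logpdf, param_domain=(-1.0 + 1e-8, 1.0 - 1e-8),
        log_param=False,
    ),
    "exp": CompetitorModel("exp", _exp_cdf, _exp_logpdf),
}


def get_model(name: str) -> CompetitorModel:
    try:
        return MODELS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}")


@dataclass(frozen=True)
class CompetitorFit:
    """MLE of a competitor model's single parameter."""

    model: str
    lambda_hat: float
    loglik: float
    n_obs: int
    se: Optional[float] = None
    converged: bool = True
    at_boundary: bool = False


def _numeric_se(negll: Callable[[float], float], lam: float) -> Optional[float]:
    h = 1e-5 * (1.0 + abs(lam))
    try:
        info = (negll(lam + h) - 2.0 * negll(lam) + negll(lam - h)) / h**2
    except (ValueError, FloatingPointError):
        return None
    if not np.isfinite(info) or info <= 0:
        return None
    return float(info**-0.5)


def fit_competitor(model, sample) -> CompetitorFit:
    """Maximum-likelihood fit of a single-parameter competitor.

    The exponential uses its closed form 1/mean; every other model is fit by
    a grid scan plus bounded refinement over its parameter domain.  A
    transmuted-HL estimate pinned to the |lambda| < 1 boundary is flagged.
    """
    if isinstance(model, str):
        model = get_model(model)
    x = _as_values(sample)
    n = x.size

    def negll(lam: float) -> float:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            lp = model.logpdf(x, lam)
        if np.any(~np.isfinite(lp)):
            return np.inf
        return -float(np.sum(lp))

    if model.name == "exp":
        lam = 1.0 / float(np.mean(x))
        return CompetitorFit("exp", lam, -negll(lam), n, se=_numeric_se(negll, lam))

    lo, hi = model.param_domain
    if model.log_param:
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), 400))
    else:
        grid = np.linspace(lo, hi, 400)
    vals = np.array([negll(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        return CompetitorFit(model.name, np.nan, -np.inf, n, converged=False)
    k = int(np.nanargmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
    )
    lam, val = float(res.x), float(res.fun)
    if val > vals[k]:
        lam, val = float(grid[k]), float(vals[k])
    at_boundary = (lam - lo) < 1e-6 * (hi - lo) or (hi - lam) < 1e-6 * (hi - lo)
    return CompetitorFit(
        model.name, lam, -val, n,
        se=_numeric_se(negll, lam), converged=bool(res.success),
        at_boundary=bool(at_boundary),
    )


# ---------------------------------------------------------------------------
# EDF statistics

def ks_test(sample, cdf: Callable[[np.ndarray], np.ndarray]) -> Tuple[float, float]:
    """Kolmogorov-Smirnov statistic and asymptotic p-value.

    D_n = max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n); the p-value is
    the survival function of the limiting Kolmogorov law at sqrt(n) D_n.
    """
    x = np.sort(_as_values(sample))
    n = x.size
    u = np.asarray(cdf(x), dtype=float)
    if np.any(~np.isfinite(u)):
        raise ValueError("cdf produced non-finite values on the sample")
    i = np.arange(1, n + 1)
    d = max(float(np.max(i / n - u)), float(np.max(u - (i - 1) / n)))
    p = float(stats.kstwobign.sf(np.sqrt(n) * d))
    return d, p


def edf_statistics(
    sample, cdf: Callable[[np.ndarray], np.ndarray], modified: bool = True
) -> Tuple[float, float]:
    """Anderson-Darling (A*) and Cramer-von Mises (W*) statistics.

    With ``modified=True`` (default) the small-sample factors
    (1 + 0.75/n + 2.25/n^2) and (1 + 0.5/n) standard in the
    distribution-fitting literature are applied.
    """
    x = np.sort(_as_values(sample))
    n = x.size
    u = np.clip(np.asarray(cdf(x), dtype=float), 1e-12, 1.0 - 1e-12)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("fitted probabilities degenerate at 0 or 1")
    i = np.arange(1, n + 1)
    w2 = float(np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2) + 1.0 / (12.0 * n))
    a2 = float(-n - np.mean((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))))
    if modified:
        a2 *= 1.0 + 0.75 / n + 2.25 / n**2
        w2 *= 1.0 + 0.5 / n
    return a2, w2


def ttt_transform(sample) -> np.ndarray:
    """Scaled total-time-on-test transform.

    Returns the (r/n, G(r/n)) pairs with
    G(r/n) = [sum_{i<=r} x_(i) + (n-r) x_(r)] / sum_i x_i; a concave curve
    diagnoses an increasing hazard rate.
    """
    x = np.sort(_as_values(sample))
    n = x.size
    if n < 2:
        raise ValueError("TTT transform needs n >= 2")
    total = float(np.sum(x))
    csum = np.cumsum(x)
    r = np.arange(1, n + 1)
    g = (csum + (n - r) * x) / total
    return np.column_stack([r / n, g])


def pp_points(sample, cdf: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Probability-probability pairs (empirical i/(n+1), fitted F(x_(i)))."""
    x = np.sort(_as_values(sample))
    n = x.size
    emp = np.arange(1, n + 1) / (n + 1.0)
    return np.column_stack([emp, np.asarray(cdf(x), dtype=float)])


# ---------------------------------------------------------------------------
# model comparison

@dataclass
class GofReport:
    """Full goodness-of-fit panel for one fitted model."""

    model: str
    fit: CompetitorFit
    neg_loglik: float
    aic: float
    A_star: float
    W_star: float
    ks: float
    ks_pvalue: float
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lambda_hat": self.fit.lambda_hat,
            "se": self.fit.se,
            "neg_loglik": self.neg_loglik,
            "A_star": self.A_star,
            "W_star": self.W_star,
            "ks": self.ks,
            "ks_pvalue": self.ks_pvalue,
            "aic": self.aic,
        }


def gof_report(model, sample, fit: Optional[CompetitorFit] = None) -> GofReport:
    """Fit one model (unless a fit is supplied) and assemble its panel."""
    if isinstance(model, str):
        model = get_model(model)
    if fit is None:
        fit = fit_competitor(model, sample)
    cdf = lambda t: model.cdf(t, fit.lambda_hat)
    d, p = ks_test(sample, cdf)
    a_star, w_star = edf_statistics(sample, cdf)
    nll = -fit.loglik
    return GofReport(
        model=model.name, fit=fit, neg_loglik=nll, aic=2.0 * 1 + 2.0 * nll,
        A_star=a_star, W_star=w_star, ks=d, ks_pvalue=p,
    )


def compare_models(sample, models: Sequence[str] = tuple(MODELS)) -> List[GofReport]:
    """Fit every requested model and rank the reports by -loglik (ascending).

    A model whose fit fails is kept in the output with the failure recorded
    in ``error`` and ranked last; one bad model never aborts the comparison.
    """
    if len(models) < 1:
        raise ValueError("at least one model required")
    reports: List[GofReport] = []
    for name in models:
        try:
            reports.append(gof_report(name, sample))
        except Exception as exc:  # recorded, not fatal
            dummy = CompetitorFit(name, np.nan, -np.inf, _as_values(sample).size,
                                  converged=False)
            reports.append(GofReport(name, dummy, np.inf, np.inf, np.nan,
                                     np.nan, np.nan, np.nan, error=str(exc)))
    reports.sort(key=lambda r: r.neg_loglik)
    return reports
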