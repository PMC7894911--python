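# olihl

Parametric survival analysis with the **odd Lindley half-logistic (OLiHL)
distribution** — a one-parameter lifetime law for right-skewed, unimodal data
with increasing hazard — and its companion machinery: four estimators of the
shape parameter, goodness-of-fit comparison against the classical
one-parameter competitors, a censored log-location-scale (AFT) regression
with residual diagnostics, and a Monte-Carlo bias/MSE study. It is aimed at
biostatisticians and reliability analysts who want a parsimonious alternative
to multi-parameter lifetime families.

## The model

Insert the half-logistic cdf G(x) = (1 − e⁻ˣ)/(1 + e⁻ˣ) into the odd
Lindley generator (the odds G/(1−G) of failure before x follow a
Lindley(λ) law). The result, for x > 0 and shape λ > 0:

```
F(x; λ) = 1 − (λeˣ + λ + 2) / (2(λ+1)) · exp(−(λ/2)(eˣ − 1))
f(x; λ) = λ²(1 + eˣ) / (4(1+λ)) · exp(x − (λ/2)(eˣ − 1))
h(x; λ) = λ²(1 + eˣ) / (2[λ(1 + e⁻ˣ) + 2e⁻ˣ])          (increasing in x)
Q(u; λ) = ln{ −(2/λ)[1 + W₋₁((1+λ)(u−1)e^{−(1+λ)})] − 1 }
```

with W₋₁ the negative Lambert-W branch; the Lambert argument provably stays
in [−1/e, 0), so the quantile function is closed-form and exact inversion
sampling is available. λ controls skewness: left-skewed for small λ,
right-skewed for large λ, nearly symmetric at λ ≈ 0.81.

Four estimators of λ are provided: maximum likelihood (the score equation
reduces to the quadratic Sλ² + (S−n)λ − 2n = 0 with S = ½Σ(eˣⁱ−1), so the
MLE is closed-form, with Wald intervals from the analytic observed
information 2n/λ² − n/(1+λ)²), least squares and weighted least squares on
the uniform-order-statistic plotting positions j/(n+1), and the
Cramér–von Mises minimum-distance criterion.

For regression, Y = log X plus location/scale gives the **LOLiHL** family;
covariates enter the location, μᵢ = xᵢᵀβ, and right-censored data are fit by
maximizing Σ_events log f + Σ_censored log S. Martingale and modified
deviance residuals are computed from the fitted survival function.

## Worked example

```python
import numpy as np
from olihl import OLiHL, OLiHLEstimator, compare_models

x = OLiHL(0.5).rvs(300, seed=42).values          # exact inversion sampling

est = OLiHLEstimator(method="mle").fit(x)
print(est.lambda_, est.se_, est.ci_)
# lambda_hat = 0.5249  se = 0.0221  95% CI = (0.4816, 0.5682)

for r in compare_models(x, ["olihl", "li", "exp"]):
    print(r.model, r.neg_loglik, r.aic, r.ks, r.ks_pvalue)
# olihl  -loglik=  319.79  AIC=  641.58  KS=0.032 (p=0.913)
# li     -loglik=  436.00  AIC=  874.00  KS=0.212 (p=0.000)
# exp    -loglik=  467.08  AIC=  936.15  KS=0.254 (p=0.000)
```

The true shape 0.5 is recovered within one standard error and the
comparison ranks the generating model first on every statistic (lower
−log-likelihood, AIC and Kolmogorov–Smirnov distance are better).

Censored regression with the sklearn-style estimator:

```python
from olihl import generate_regression, LOLiHLRegressor

d = generate_regression(lam=2.0, beta=(2.0, -0.5, -0.01), sigma=0.8,
                        n=600, censor_fraction=0.2, seed=11)
reg = LOLiHLRegressor().fit(d.X[:, 1:], d.y, event=d.delta)
print(reg.lambda_, reg.intercept_, reg.coef_, reg.sigma_, reg.aic_)
# lambda=2.635 intercept=2.040 coef=[-0.5114 -0.0069] sigma=0.736 AIC=1142.72
```

Every generating coefficient lies inside its Wald interval
(`reg.result_.se`).

A `click` CLI mirrors the library: `olihl fit`, `olihl gof`,
`olihl regress`, `olihl simulate`, `olihl generate` (see `olihl --help`).
Published datasets can be analyzed by dropping CSVs into `data/`
(`carbon_fibers.csv` with a `time` column; `hiv.csv` with `time`, `cens`,
`drug`, `age`); the optional tests in `tests/test_external_data.py` then
check the fits against the published tables.

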