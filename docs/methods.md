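# Methods

## The distribution

The OLiHL law composes the half-logistic baseline with the odd Lindley
generator: if T is half-logistic with cdf G and the odds G/(1−G) of failing
before t are themselves Lindley(λ)-distributed, the resulting lifetime
distribution has the closed-form cdf, pdf, hazard and quantile given in the
README. Key structural facts this package relies on:

- the hazard is increasing for every λ > 0, so the family is only
  appropriate for aging/wear-out phenomena (the TTT transform is provided to
  check this empirically — a concave TTT curve supports an increasing
  hazard);
- the quantile function is closed-form through the Lambert W₋₁ branch, and
  the Lambert argument (1+λ)(u−1)e^{−(1+λ)} lies in [−1/e, 0) for all λ > 0,
  u ∈ (0,1) because t e^{−t} ≤ 1/e; sampling is exact inversion. In floating
  point the argument underflows to −0 for λ ≳ 745, which caps the usable
  shape range well above anything data can identify;
- moment expansions are not used; mean, variance, skewness and kurtosis are
  adaptive quadrature of x^r f(x) over (0, Q(1−10⁻¹²)) with absolute
  tolerance 10⁻¹⁰ (the data-driven upper limit avoids overflow of the eˣ
  terms at an infinite limit). Non-convergent quadrature raises rather than
  returning a value.

Shape behaviour, computed by that quadrature: the mean decreases in λ
throughout; the variance decreases for λ ≳ 0.2 but has a shallow maximum
near λ ≈ 0.15, so "variance decreasing in λ" is only asserted on λ ≥ 0.25.
Skewness is negative (left-skewed) for small λ, positive for large λ, and
crosses zero at λ = 0.8117; `symmetry_lambda()` locates this root by Brent
bracketing on [0.1, 5] and the value is quoted to two decimals since the
skewness is extremely flat near the root.

Numerical conventions: cdf at x < 0 returns 0 (and sf 1, pdf 0) so EDF
statistics compose cleanly; all likelihood-facing code uses log-space forms
(`expm1`, `logaddexp`); observations with x > ~700, where eˣ overflows a
double, raise `OverflowError` instead of silently producing ±inf.

## Estimation of λ

The score equation of the log-likelihood
ℓ(λ) = 2n lnλ − n ln(4+4λ) + Σln(1+eˣⁱ) − (λ/2)Σ(eˣⁱ−1) + Σxᵢ
rearranges to Sλ² + (S−n)λ − 2n = 0 with S = ½Σ(eˣⁱ−1) > 0, whose unique
positive root is the MLE. We use this closed form (an iterative solver is
retained only as a test oracle); the standard error is the inverse square
root of the analytic observed information 2n/λ̂² − n/(1+λ̂)², and the
confidence interval is Wald with normal quantiles (default level 95%).

The LSE/WLSE/CVME objectives — squared distances between the fitted cdf at
the order statistics and the plotting positions j/(n+1) (weighted by the
inverse Beta order-statistic variance (n+1)²(n+2)/(j(n−j+1)) for WLSE) or
(2j−1)/(2n) plus the 1/(12n) constant for CVME — are minimized over
λ ∈ [10⁻⁶, 10³] by a 400-point log-λ grid scan followed by bounded Brent
refinement in the winning grid cell. The grid-then-refine scheme plays the
role of a multi-start: the objectives are smooth but can be flat in λ, and
the scan makes the minimizer initialization-free and order-invariant.
Ties resolve to the smallest objective found.

## Goodness of fit

A*/W* are the Anderson–Darling and Cramér–von Mises EDF statistics with the
small-sample modification factors (1 + 0.75/n + 2.25/n²) and (1 + 0.5/n)
that are the de-facto convention in the distribution-fitting literature;
the unmodified statistics are available via `modified=False`. Fitted
probabilities are clipped to [10⁻¹², 1−10⁻¹²] before the A* logarithms. The
KS p-value uses the asymptotic Kolmogorov law at √n·Dₙ, matching common
software output at moderate n; it is a plug-in p-value (the fitted
parameter is treated as known), as is conventional in this literature.
Model ranking uses −ℓ as the primary key — with one parameter per model the
AIC ordering is identical — and the full panel is always reported. A model
whose fit fails is recorded with its error and ranked last rather than
aborting the comparison.

The transmuted half-logistic parameter is constrained to |λ| < 1; estimates
within 10⁻⁶ of the boundary are flagged (`at_boundary`), as OLiHL-like data
routinely push it there. The inverse Lindley is implemented with the
standard e^{−λ/x} kernel (the only form that is a distribution function).

## Censored LOLiHL regression

With z = (y−μ)/σ and w = e^z the LOLiHL log-density and log-survival are

    log f = 2lnλ − ln(4σ(λ+1)) + ln(1+e^w) + z + w − (λ/2)(e^w − 1)
    log S = ln(λ + λe^w + 2) − ln(2λ+2) − (λ/2)(e^w − 1)

The (e^w − 1) exponent in log S is forced by the boundary condition
S(−∞) = 1 and by consistency with the lifetime-scale survival function
under y = log x; the alternative (e^w + 1) variant that sometimes appears
in print fails both (it gives S(−∞) = e^{−λ}) and is kept only behind
`convention="printed"` for forensic comparison. A unit test encodes the
boundary argument.

Fitting maximizes the right-censored likelihood over (lnλ, β, lnσ) — the
log transforms make the positivity constraints implicit — by BFGS
multi-started at λ₀ ∈ {0.5, 5, 20} (the λ surface can be flat and the
published-scale estimates can be large), with β₀ from least squares of y on
X and σ₀ from the residual standard deviation, followed by a Nelder–Mead
polish (BFGS often stops with a precision-loss flag exactly at the optimum;
the polish verifies it). Standard errors come from the central-difference
observed information (step 10⁻⁵(1+|θ|) per coordinate on the transformed
scale) mapped to the natural scale by the delta method; Wald z = β̂/se with
two-sided normal p-values; AIC = 2(k+2) − 2ℓ counting λ, all β's and σ.
A singular or non-positive-definite information matrix produces a warning
and absent standard errors, never a crash.

Residuals: martingale rᴹ = δ + log Ŝ(y) (events in (−∞, 1], censored rows
≤ 0) and modified deviance rᴰ = sign(rᴹ)·√(−2[rᴹ + log(1−rᴹ)]) for events,
sign(rᴹ)·√(−2rᴹ) for censored rows. An event with rᴹ = 1 exactly has an
infinite deviance residual; this is flagged with a warning rather than
masked.

## Synthetic data

`generate_sample` draws OLiHL lifetimes by exact inversion.
`generate_regression` emulates an epidemiological survival study: a binary
exposure covariate ~ Bernoulli(0.5) and an age covariate ~ Uniform(20, 60),
log-lifetimes μᵢ + σ log Xᵢ with Xᵢ ~ OLiHL(λ), and right-censoring times
from the same model location-shifted by the empirical (1 − c) quantile of
the latent gaps so the realized censored share matches the request to
within about 1/n. Defaults (λ = 2, β = (2.0, −0.5, −0.01), σ = 0.8, 20%
censoring) produce moderately left-skewed log-lifetimes with both a strong
binary and a weak continuous effect, the regime the regression model
targets. What the generator does **not** emulate: covariate-dependent or
informative censoring, ties/rounding of recorded times, covariate
measurement error, or model misspecification — so passing recovery tests
demonstrate correctness of the estimator under the model, not robustness on
real data.

## Study sizes used by the tests

The Monte-Carlo bias/MSE study runs at λ = 0.1 over n = 20, 25, …, 100.
The package default is N = 1000 replications; the test suite runs N = 200,
a size at which the convergence-to-zero trends it asserts (endpoint
decrease and a negative log-log MSE slope) are already unambiguous.
Method *ranking* is deliberately not asserted — the four estimators are
close throughout and only qualitative convergence claims are robust.
Per-replicate seeds are derived as seed + 1000·n + r so all methods see
identical samples (paired comparison) and every run is reproducible.

Estimator consistency is checked at n ∈ {50, 200, 1000}; Wald-interval
coverage at n = 200 over 400 replications (±3% of nominal 95%); regression
parameter recovery at n = 600 (3-SE band per parameter) and n = 2000 in the
property panel.

## Known limitations

- The distribution cannot represent decreasing or bathtub hazards.
- Estimation assumes complete (uncensored) univariate samples; censoring is
  handled only in the regression module.
- The asymptotic KS p-value is approximate below n ≈ 40 and ignores
  parameter-estimation effects (as is standard practice in this family of
  comparisons).
- Quantile evaluation loses the Lambert branch for λ ≳ 745 (argument
  underflow); such shapes are far outside the identifiable range.
- Published-data checks (the n = 66 carbon-fiber breaking-stress table and
  the n = 100 HIV+ regression table) activate only when the user supplies
  the corresponding CSVs under `data/`; the datasets are not redistributed
  with the package.
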