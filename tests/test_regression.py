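"""Censored LOLiHL location-scale regression and its residuals."""

import numpy as np
import pytest
from scipy import integrate

from olihl import (
    LOLiHLParams,
    LOLiHLRegressor,
    OLiHL,
    SurvivalDataset,
    censored_loglik,
    fit_regression,
    generate_regression,
    lolihl_logpdf,
    lolihl_logsf,
    residuals,
)
from olihl.regression import lolihl_sf, lolihl_cdf


class TestLolihlDensity:
    @pytest.mark.parametrize("lam", [0.5, 2.0])
    @pytest.mark.parametrize("y", [-1.0, 0.0, 1.0])
    def test_change_of_variables(self, lam, y):
        # f_Y(y) = f_X(e^y) e^y for Y = log X
        a = float(lolihl_logpdf(y, LOLiHLParams(lam)))
        b = float(OLiHL(lam).logpdf(np.exp(y))) + y
        assert a == pytest.approx(b, abs=1e-12)

    def test_normalization(self):
        p = LOLiHLParams(1.0)
        val, _ = integrate.quad(lambda y: float(np.exp(lolihl_logpdf(y, p))),
                                -30, 2.5, limit=300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_location_scale_identity(self):
        p = LOLiHLParams(0.8, mu=1.5, sigma=0.4)
        std = LOLiHLParams(0.8)
        for y in (-0.5, 1.0, 2.0):
            a = float(lolihl_logpdf(y, p))
            b = float(lolihl_logpdf((y - 1.5) / 0.4, std)) - np.log(0.4)
            assert a == pytest.approx(b, abs=1e-12)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            lolihl_logpdf(10.0, LOLiHLParams(1.0))


class TestLolihlSurvival:
    def test_boundary_limits_corrected(self):
        p = LOLiHLParams(1.0)
        assert float(lolihl_sf(-30.0, p)) == pytest.approx(1.0, abs=1e-10)
        assert float(lolihl_sf(2.5, p)) < 1e-6

    def test_printed_convention_fails_boundary(self):
        # the "+1" exponent variant cannot reach S(-inf) = 1
        p = LOLiHLParams(1.0)
        assert float(lolihl_sf(-30.0, p, convention="printed")) < 0.5

    def test_matches_lifetime_scale_survival(self):
        for lam in (0.5, 2.0):
            d = OLiHL(lam)
            for y in (-1.0, 0.2, 1.0):
                a = float(lolihl_sf(y, LOLiHLParams(lam)))
                b = float(d.sf(np.exp(y)))
                assert a == pytest.approx(b, rel=1e-10)

    def test_strictly_decreasing_and_complement(self):
        p = LOLiHLParams(0.7, mu=0.3, sigma=1.2)
        y = np.linspace(-8, 1.8, 200)  # below the deep-tail underflow region
        S = np.array([float(lolihl_sf(t, p)) for t in y])
        assert np.all(np.diff(S) < 0)
        F = np.array([float(lolihl_cdf(t, p)) for t in y])
        np.testing.assert_allclose(S + F, 1.0, atol=1e-10)

    def test_bad_convention(self):
        with pytest.raises(ValueError):
            lolihl_logsf(0.0, LOLiHLParams(1.0), convention="other")


class TestCensoredLoglik:
    def test_no_censoring_equals_iid_loglik(self, regression_data):
        d = regression_data
        full = SurvivalDataset(y=d.y, delta=np.ones(d.n, dtype=int), X=d.X)
        beta = np.zeros(d.k); beta[0] = 2.0
        ll = censored_loglik(full, 1.5, beta, 0.9)
        direct = sum(
            float(lolihl_logpdf(yi, LOLiHLParams(1.5, float(mi), 0.9)))
            for yi, mi in zip(d.y, d.X @ beta)
        )
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_all_censored_equals_sum_logsf(self, regression_data):
        d = regression_data
        cens = SurvivalDataset(y=d.y, delta=np.zeros(d.n, dtype=int), X=d.X)
        beta = np.zeros(d.k); beta[0] = 2.0
        ll = censored_loglik(cens, 1.5, beta, 0.9)
        direct = sum(
            float(lolihl_logsf(yi, LOLiHLParams(1.5, float(mi), 0.9)))
            for yi, mi in zip(d.y, d.X @ beta)
        )
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_matches_expanded_form(self):
        # the branch-sum likelihood equals its fully expanded algebraic form
        rng = np.random.default_rng(21)
        n = 5
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.normal(0.5, 0.3, size=n)
        delta = np.array([1, 0, 1, 1, 0])
        data = SurvivalDataset(y=y, delta=delta, X=X)
        lam, beta, sigma = 1.3, np.array([0.4, 0.2]), 0.7
        z = (y - X @ beta) / sigma
        w = np.exp(z)
        F = delta == 1
        r = int(F.sum())
        expanded = (
            r * np.log(lam**2 / (sigma * (4 * lam + 4)))
            + np.sum(np.log1p(np.exp(w[F])))
            + np.sum(z[F] + w[F])
            - np.sum(lam / 2 * np.expm1(w[F]))
            + np.sum(np.log((lam + lam * np.exp(w[~F]) + 2) / (2 * lam + 2)))
            - np.sum(lam / 2 * np.expm1(w[~F]))
        )
        assert censored_loglik(data, lam, beta, sigma) == pytest.approx(
            expanded, abs=1e-10
        )


class TestFit:
    def test_parameter_recovery(self, regression_data):
        truth = {"lam": 2.0, "beta": np.array([2.0, -0.5, -0.01]), "sigma": 0.8}
        fit = fit_regression(regression_data)
        assert fit.converged
        assert fit.se is not None
        theta_hat = np.concatenate([[fit.lam], fit.beta, [fit.sigma]])
        theta_true = np.concatenate([[truth["lam"]], truth["beta"],
                                     [truth["sigma"]]])
        assert np.all(np.abs(theta_hat - theta_true) < 3 * fit.se)

    def test_aic_identity(self, regression_data):
        fit = fit_regression(regression_data)
        assert fit.aic - 2 * fit.n_params + 2 * fit.loglik == pytest.approx(0.0)

    def test_wald_table_shapes(self, regression_data):
        fit = fit_regression(regression_data)
        k = regression_data.k
        assert fit.beta.shape == (k,)
        assert fit.se.shape == (k + 2,)
        assert fit.z_stat.shape == (k,)
        assert np.all((fit.p_values >= 0) & (fit.p_values <= 1))

    def test_too_few_rows(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError):
            fit_regression(SurvivalDataset(y=np.zeros(3),
                                           delta=np.ones(3, dtype=int), X=X))


class TestResiduals:
    def test_martingale_bounds(self, regression_data):
        fit = fit_regression(regression_data)
        rM = fit.martingale
        assert np.all(rM <= 1.0 + 1e-12)
        assert np.all(rM[regression_data.delta == 0] <= 0.0 + 1e-12)

    def test_limit_values(self):
        # S(y) -> 1 far in the left tail: event gives r_M -> 1, censored -> 0
        X = np.ones((2, 1))
        data_ev = SurvivalDataset(y=np.array([-25.0, 0.0]),
                                  delta=np.array([1, 1]), X=X)
        r = residuals(data_ev, 1.0, np.array([0.0]), 1.0)
        assert r["martingale"][0] == pytest.approx(1.0, abs=1e-9)
        data_c = SurvivalDataset(y=np.array([-25.0, 0.0]),
                                 delta=np.array([0, 0]), X=X)
        r = residuals(data_c, 1.0, np.array([0.0]), 1.0)
        assert r["martingale"][0] == pytest.approx(0.0, abs=1e-9)
        assert r["deviance"][0] == pytest.approx(0.0, abs=1e-4)

    def test_martingale_sum_near_zero(self, regression_data):
        # soft identity for a well-specified fit
        fit = fit_regression(regression_data)
        assert abs(np.mean(fit.martingale)) < 0.1

    def test_deviance_finite_for_interior_points(self, regression_data):
        fit = fit_regression(regression_data)
        assert np.all(np.isfinite(fit.deviance))


class TestSklearnRegressor:
    def test_fit_predict_clone(self, regression_data):
        from sklearn.base import clone

        d = regression_data
        reg = LOLiHLRegressor().fit(d.X[:, 1:], d.y, event=d.delta)
        assert reg.coef_.shape == (2,)
        mu = reg.predict(d.X[:2, 1:])
        np.testing.assert_allclose(mu, reg.intercept_ + d.X[:2, 1:] @ reg.coef_)
        clone(reg)

    def test_matches_functional_api(self, regression_data):
        d = regression_data
        reg = LOLiHLRegressor().fit(d.X[:, 1:], d.y, event=d.delta)
        fit = fit_regression(d)
        assert reg.lambda_ == pytest.approx(fit.lam, rel=1e-6)
        np.testing.assert_allclose(
            np.concatenate([[reg.intercept_], reg.coef_]), fit.beta, rtol=1e-6
        )

    def test_predict_survival_monotone(self, regression_data):
        d = regression_data
        reg = LOLiHLRegressor().fit(d.X[:, 1:], d.y, event=d.delta)
        times = np.array([1.0, 3.0, 6.0, 10.0])
        S = reg.predict_survival(d.X[:3, 1:], times)
        assert S.shape == (3, 4)
        assert np.all(np.diff(S, axis=1) <= 1e-12)
        assert np.all((S >= 0) & (S <= 1))

    def test_log_time_input(self, regression_data):
        d = regression_data
        reg = LOLiHLRegressor(log_time=True).fit(
            d.X[:, 1:], np.exp(d.y), event=d.delta
        )
        fit = fit_regression(d)
        assert reg.lambda_ == pytest.approx(fit.lam, rel=1e-5)


class TestDatasetValidation:
    def test_bad_delta(self):
        with pytest.raises(ValueError):
            SurvivalDataset(y=np.zeros(2), delta=np.array([0, 2]),
                            X=np.ones((2, 1)))

    def test_mismatched_rows(self):
        with pytest.raises(ValueError):
            SurvivalDataset(y=np.zeros(3), delta=np.zeros(2),
                            X=np.ones((3, 1)))

    def test_rank_deficiency_warns(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.warns(UserWarning):
            SurvivalDataset(y=np.zeros(5), delta=np.ones(5, dtype=int), X=X)
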