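"""Quasi-Poisson IRLS, PACF, and the trend-df selection criterion."""

import numpy as np
import pytest
from scipy import linalg, optimize

from dlagheat.qpglm import fit_quasipoisson, pacf, select_trend_df


@pytest.fixture(scope="module")
def small_design():
    rng = np.random.default_rng(12)
    n, p = 200, 6
    X = np.column_stack([np.ones(n), rng.normal(0, 0.5, (n, p - 1))])
    beta_true = np.array([1.2, 0.3, -0.2, 0.1, 0.05, -0.4])
    mu = np.exp(X @ beta_true)
    y = rng.poisson(mu)
    return y, X, beta_true


class TestQuasiPoissonFit:
    def test_intercept_only_closed_form(self):
        y = np.array([0, 3, 1, 4, 2, 2, 5, 1])
        fit = fit_quasipoisson(y, np.ones((len(y), 1)))
        assert fit.coef[0] == pytest.approx(np.log(y.mean()), abs=1e-10)

    def test_matches_direct_likelihood_maximization(self, small_design):
        """IRLS solution agrees with an independent Newton maximisation of
        the Poisson log-likelihood to < 1e-6 relative."""
        y, X, _ = small_design
        fit = fit_quasipoisson(y, X)

        def negll(b):
            eta = X @ b
            return -(y @ eta - np.exp(eta).sum())

        def grad(b):
            return -X.T @ (y - np.exp(X @ b))

        def hess(b):
            mu = np.exp(X @ b)
            return X.T @ (X * mu[:, None])

        b = np.zeros(X.shape[1])
        for _ in range(50):
            step = linalg.solve(hess(b), grad(b))
            b = b - step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert np.max(np.abs(fit.coef - b) / np.maximum(np.abs(b), 1e-8)) < 1e-6
        # stationarity at the reported coefficients
        assert np.max(np.abs(grad(fit.coef))) < 1e-6

    def test_matches_statsmodels_oracle(self, small_design):
        sm = pytest.importorskip("statsmodels.api")
        y, X, _ = small_design
        fit = fit_quasipoisson(y, X)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coef, res.params, atol=1e-8)
        phi_sm = res.pearson_chi2 / res.df_resid
        assert fit.dispersion == pytest.approx(phi_sm, rel=1e-8)
        assert np.allclose(fit.vcov, phi_sm * res.cov_params(), rtol=1e-6)

    def test_dispersion_near_one_for_pure_poisson(self):
        rng = np.random.default_rng(2024)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(0, 0.4, n)])
        y = rng.poisson(np.exp(X @ np.array([1.0, 0.3])))
        fit = fit_quasipoisson(y, X)
        assert 0.9 < fit.dispersion < 1.1

    def test_vcov_scales_with_dispersion(self, small_design):
        """Quasi-Poisson vcov is phi * (X'WX)^-1, so vcov/phi is invariant."""
        y, X, _ = small_design
        fit = fit_quasipoisson(y, X)
        base = fit.vcov / fit.dispersion
        xtwx_inv = np.linalg.inv(X.T @ (X * fit.fitted[:, None]))
        assert np.allclose(base, xtwx_inv, rtol=1e-8)

    def test_zero_holiday_column_drop_is_neutral(self, small_design):
        """Removing an all-zero column leaves the remaining coefficients
        untouched (a zero column is rejected as rank deficient anyway)."""
        y, X, _ = small_design
        fit = fit_quasipoisson(y, X)
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_quasipoisson(y, np.column_stack([X, np.zeros(len(y))]))
        again = fit_quasipoisson(y, X)
        assert np.allclose(fit.coef, again.coef, atol=1e-10)

    def test_collinear_columns_named(self, small_design):
        y, X, _ = small_design
        Xbad = np.column_stack([X, X[:, 1] * 2.0])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_quasipoisson(y, Xbad)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_quasipoisson(np.array([1.0, -2.0]), np.ones((2, 1)))
        with pytest.raises(ValueError):
            fit_quasipoisson(np.array([1, 2]), np.full((2, 1), np.nan))


class TestPACF:
    def test_matches_yule_walker_toeplitz_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 400)
        x = np.convolve(x, [1.0, 0.5, 0.2], mode="valid")
        got = pacf(x, 10)
        xc = x - x.mean()
        n = len(xc)
        rho = np.array([xc[: n - k] @ xc[k:] for k in range(11)]) / (xc @ xc)
        expect = []
        for k in range(1, 11):
            phi = linalg.solve_toeplitz((rho[:k], rho[:k]), rho[1 : k + 1])
            expect.append(phi[-1])
        assert np.allclose(got, expect, atol=1e-10)

    def test_white_noise_within_null_band(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0, 1, 5000)
        assert np.max(np.abs(pacf(x, 20))) < 3 / np.sqrt(5000)

    def test_ar1_recovered_at_lag_one(self):
        rng = np.random.default_rng(9)
        n, rho = 20000, 0.6
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(0, 1, n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        p = pacf(x, 6)
        assert p[0] == pytest.approx(rho, abs=0.03)
        assert np.max(np.abs(p[1:])) < 0.03

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant|variance"):
            pacf(np.full(100, 1.5), 5)


class TestSelectTrendDf:
    def test_single_candidate_returned_without_search(self):
        df, scores = select_trend_df(
            np.array([1, 2, 3]), lambda d: np.ones((3, 1)), [3]
        )
        assert df == 3 and scores == {}

    def test_seasonal_truth_prefers_flexible_spline(self):
        """Counts with strong annual seasonality: a 3 df/yr trend spline
        leaves less residual autocorrelation than 1 df/yr."""
        from dlagheat.basis import ns_eval, trend_spline_spec

        rng = np.random.default_rng(55)
        n = 520
        t = np.arange(n, dtype=float)
        mu = np.exp(1.3 + 0.6 * np.cos(2 * np.pi * t / 52.18))
        y = rng.poisson(mu)

        def make_design(df_per_year):
            df = max(2, int(round(df_per_year * n / 52.18)))
            return np.column_stack([
                np.ones(n), ns_eval(t, trend_spline_spec(n, df)).values,
            ])

        best, scores = select_trend_df(y, make_design, [1, 3], pacf_max_lag=52)
        assert scores[3] < scores[1]
        assert best == 3

    def test_criterion_reproducible_from_residuals(self):
        from dlagheat.basis import ns_eval, trend_spline_spec
        from dlagheat.qpglm import fit_quasipoisson

        rng = np.random.default_rng(56)
        n = 260
        t = np.arange(n, dtype=float)
        y = rng.poisson(np.exp(1.0 + 0.3 * np.sin(2 * np.pi * t / 52.18)))

        def make_design(df_per_year):
            df = max(2, int(round(df_per_year * n / 52.18)))
            return np.column_stack([
                np.ones(n), ns_eval(t, trend_spline_spec(n, df)).values,
            ])

        best, scores = select_trend_df(y, make_design, [2, 3], pacf_max_lag=26)
        fit = fit_quasipoisson(y, make_design(best))
        recomputed = float(np.sum(np.abs(pacf(fit.deviance_residuals, 26))))
        assert recomputed == pytest.approx(scores[best], abs=1e-12)
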