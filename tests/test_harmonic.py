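"""Harmonic regression: design, GLS/REML estimation, amplitude and trough.

The independent oracle for the AR(1)/REML machinery is a brute-force
full-matrix implementation: the AR(1) covariance is built explicitly as a
Toeplitz matrix, the GLS solution and restricted likelihood are computed
with dense linear algebra, and rho is found by exhaustive grid search.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import toeplitz

from conftest import make_ar1, model_series
from retivel.harmonic import (
    HarmonicFit,
    PixelSeries,
    build_design_matrix,
    fit_harmonic_regression,
    hrw_amplitude,
    periodic_component,
    reml_profile,
    select_order_aic,
    time_to_trough,
)

RHO_GRID = np.round(np.arange(-0.99, 0.991, 0.01), 2)


def oracle_reml(y, X, rho):
    """Restricted log-likelihood via explicit dense AR(1) covariance."""
    n, p = X.shape
    C = toeplitz(rho ** np.arange(n)) / (1.0 - rho**2)
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    beta = np.linalg.solve(XtCiX, X.T @ Ci @ y)
    r = y - X @ beta
    rss = float(r @ Ci @ r)
    sigma2 = rss / (n - p)
    _, logdet_c = np.linalg.slogdet(C)
    _, logdet_x = np.linalg.slogdet(XtCiX)
    ll = -0.5 * ((n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
                 + logdet_c + logdet_x)
    return ll, beta


def oracle_grid_fit(y, X):
    """Exhaustive rho-grid REML maximization with exact GLS at each rho."""
    lls = [oracle_reml(y, X, r)[0] for r in RHO_GRID]
    best = int(np.argmax(lls))
    return RHO_GRID[best], oracle_reml(y, X, RHO_GRID[best])[1]


class TestDesignMatrix:
    def test_single_cycle_drops_outlying_knot(self):
        t = np.array([0.25, 0.5, 0.75, 1.0])
        with pytest.warns(RuntimeWarning, match="knot"):
            d = build_design_matrix(t, order=1, knots=(1.0, 2.0))
        # intercept, t, (t-1)_+ is all zero at t<=1 -> dropped too? (t-1)_+
        # is zero everywhere on this grid, so both knots drop
        assert d.X.shape[1] == 4
        assert d.retained_knots == ()

    def test_three_cycles_two_harmonics_has_eight_columns(self, t_307):
        d = build_design_matrix(t_307, order=2, knots=(1.0, 2.0))
        assert d.X.shape == (307, 8)
        assert d.retained_knots == (1.0, 2.0)

    def test_truncated_linear_terms(self, t_307):
        d = build_design_matrix(t_307, order=1, knots=(1.0, 2.0))
        knot1 = d.X[:, 2]
        assert knot1[t_307 <= 1.0].max() == 0.0          # (z)_+ = 0 for z <= 0
        idx = np.searchsorted(t_307, 1.5)
        assert knot1[idx] == pytest.approx(t_307[idx] - 1.0)  # (z)_+ = z for z > 0

    def test_pi_basis_has_period_two_fundamental(self):
        t = np.linspace(0.01, 2.0, 200)
        d = build_design_matrix(t, order=1, knots=(1.0,), basis="pi")
        np.testing.assert_allclose(d.X[:, -2], np.cos(np.pi * t))

    def test_rejects_bad_order(self, t_307):
        with pytest.raises(ValueError):
            build_design_matrix(t_307, order=0)


class TestNoiselessRecovery:
    def test_pure_cosine_recovered_exactly(self, t_307):
        y = 2.0 + np.cos(2 * np.pi * t_307)
        fit = fit_harmonic_regression(PixelSeries(y=y, t=t_307), order=2)
        assert fit.a0 == pytest.approx(2.0, abs=1e-8)
        assert fit.harmonics[0][0] == pytest.approx(1.0, abs=1e-8)
        for coef in (fit.harmonics[0][1], *fit.harmonics[1], *fit.spline):
            assert coef == pytest.approx(0.0, abs=1e-8)
        assert fit.hrw_amplitude == pytest.approx(2.0, abs=1e-8)
        assert fit.time_to_trough == pytest.approx(0.5, abs=1e-6)

    def test_full_model_coefficients_recovered(self, t_307):
        y = model_series(t_307, a0=7.0, harmonics=((1.2, -0.4), (0.3, 0.1)),
                         drift=(2.0, -3.0, 1.5))
        fit = fit_harmonic_regression(PixelSeries(y=y, t=t_307), order=2)
        assert fit.harmonics[0] == pytest.approx((1.2, -0.4), abs=1e-8)
        assert fit.harmonics[1] == pytest.approx((0.3, 0.1), abs=1e-8)
        assert fit.spline[1:] == pytest.approx((2.0, -3.0, 1.5), abs=1e-8)

    def test_constant_series_flagged_zero_amplitude(self, t_307):
        fit = fit_harmonic_regression(
            PixelSeries(y=np.full_like(t_307, 9.0), t=t_307), order=2)
        assert fit.hrw_amplitude == 0.0
        assert math.isnan(fit.time_to_trough)
        assert "degenerate" in fit.flags


class TestGLSAgainstOracles:
    def test_gls_at_rho_zero_is_ols(self, t_307):
        rng = np.random.default_rng(11)
        y = model_series(t_307) + rng.normal(0, 0.3, len(t_307))
        X = build_design_matrix(t_307, order=2).X
        from retivel.harmonic import _gls_at_rho

        beta, _, _, _ = _gls_at_rho(y, X, 0.0)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_array_equal(beta, beta_ols)

    def test_gls_matches_statsmodels_at_fixed_rho(self, t_307):
        import statsmodels.api as sm

        from retivel.harmonic import _gls_at_rho

        rng = np.random.default_rng(5)
        y = model_series(t_307) + make_ar1(rng, len(t_307), 0.6, 0.25)
        X = build_design_matrix(t_307, order=2).X
        for rho in (0.3, 0.6, -0.4):
            C = toeplitz(rho ** np.arange(len(y))) / (1 - rho**2)
            expected = sm.GLS(y, X, sigma=C).fit().params
            beta, *_ = _gls_at_rho(y, X, rho)
            np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_reml_profile_matches_dense_oracle(self, t_300):
        rng = np.random.default_rng(17)
        y = model_series(t_300) + make_ar1(rng, len(t_300), 0.5, 0.2)
        X = build_design_matrix(t_300, order=2).X
        for rho in (-0.5, 0.0, 0.45, 0.8):
            assert reml_profile(y, X, rho) == pytest.approx(
                oracle_reml(y, X, rho)[0], abs=1e-6)

    def test_reml_at_zero_equals_ols_restricted_likelihood(self, t_300):
        rng = np.random.default_rng(23)
        y = model_series(t_300) + rng.normal(0, 0.3, len(t_300))
        X = build_design_matrix(t_300, order=2).X
        n, p = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        sigma2 = rss / (n - p)
        _, logdet_x = np.linalg.slogdet(X.T @ X)
        expected = -0.5 * ((n - p) * (math.log(2 * math.pi * sigma2) + 1)
                           + logdet_x)
        assert reml_profile(y, X, 0.0) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("rho_true", [0.0, 0.5, 0.8])
    def test_fit_agrees_with_grid_oracle(self, t_307, rho_true):
        rng = np.random.default_rng(int(100 * rho_true) + 1)
        y = model_series(t_307) + make_ar1(rng, len(t_307), rho_true, 0.2)
        series = PixelSeries(y=y, t=t_307)
        fit = fit_harmonic_regression(series, order=2)
        X = build_design_matrix(t_307, order=2).X
        rho_grid, beta_grid = oracle_grid_fit(y, X)
        assert abs(fit.rho - rho_grid) <= 0.01
        impl_beta = [fit.a0, fit.spline[1], fit.spline[2], fit.spline[3],
                     *fit.harmonics[0], *fit.harmonics[1]]
        np.testing.assert_allclose(impl_beta, beta_grid, atol=2e-3)

    def test_rho_domain_error(self, t_300):
        X = build_design_matrix(t_300, order=1).X
        with pytest.raises(ValueError):
            reml_profile(np.sin(t_300), X, 1.0)


class TestAmplitudeAndTrough:
    def _fit(self, harmonics, spline=(0.0, 0.0, 0.0, 0.0), a0=0.0):
        return HarmonicFit(a0=a0, harmonics=harmonics, spline=spline, rho=0.0,
                           sigma_u=0.0, loglik_reml=0.0, loglik_ml=0.0, aic=0.0,
                           hrw_amplitude=0.0, time_to_trough=0.0)

    def test_periodic_component_values(self):
        f = self._fit(((1.0, 0.0),))
        assert periodic_component(f, 0.0) == pytest.approx(1.0)
        assert periodic_component(f, 0.5) == pytest.approx(-1.0)
        assert periodic_component(self._fit(((0.0, 1.0),)), 0.25) == pytest.approx(1.0)
        assert periodic_component(self._fit(((1.0, 0.0), (1.0, 0.0))), 0.0) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "harmonics, amp, trough",
        [
            (((1.0, 0.0),), 2.0, 0.5),
            (((-1.0, 0.0),), 2.0, 0.0),
            # stationary-point analysis: min of cos u + cos 2u at cos u = -1/4
            (((1.0, 0.0), (1.0, 0.0)), 3.125, math.acos(-0.25) / (2 * math.pi)),
        ],
    )
    def test_closed_form_extrema(self, harmonics, amp, trough):
        f = self._fit(harmonics)
        assert hrw_amplitude(f) == pytest.approx(amp, abs=1e-7)
        assert time_to_trough(f) == pytest.approx(trough, abs=1e-6)

    def test_zero_wave_has_undefined_trough(self):
        f = self._fit(((0.0, 0.0),))
        assert hrw_amplitude(f) == 0.0
        assert math.isnan(time_to_trough(f))

    @given(
        a1=st.floats(-2, 2), b1=st.floats(-2, 2), a2=st.floats(-1, 1),
        b2=st.floats(-1, 1), a0=st.floats(-50, 50), s1=st.floats(-5, 5),
        s2=st.floats(-5, 5), s3=st.floats(-5, 5),
    )
    @settings(deadline=None, max_examples=40)
    def test_invariant_to_intercept_and_spline(self, a1, b1, a2, b2, a0, s1, s2, s3):
        base = self._fit(((a1, b1), (a2, b2)))
        shifted = self._fit(((a1, b1), (a2, b2)), spline=(0.0, s1, s2, s3), a0=a0)
        assert hrw_amplitude(base) == hrw_amplitude(shifted)
        t0, t1 = time_to_trough(base), time_to_trough(shifted)
        assert (math.isnan(t0) and math.isnan(t1)) or t0 == t1
        if hrw_amplitude(base) > 0:
            assert 0.0 <= t0 < 1.0


class TestOrderSelection:
    def test_max_order_one_returns_one(self, t_300):
        rng = np.random.default_rng(2)
        y = model_series(t_300) + rng.normal(0, 0.3, len(t_300))
        assert select_order_aic(PixelSeries(y=y, t=t_300), max_order=1) == 1

    def test_pure_first_harmonic_prefers_order_one(self, t_300):
        rng = np.random.default_rng(3)
        y = model_series(t_300, harmonics=((1.5, -0.5),)) \
            + rng.normal(0, 0.1, len(t_300))
        assert select_order_aic(PixelSeries(y=y, t=t_300), max_order=3) == 1

    def test_two_harmonic_content_prefers_order_two(self, t_300):
        picks = []
        for seed in range(12):
            rng = np.random.default_rng(1000 + seed)
            y = model_series(t_300) + make_ar1(rng, len(t_300), 0.3, 0.25)
            picks.append(select_order_aic(PixelSeries(y=y, t=t_300), max_order=3))
        assert sum(p == 2 for p in picks) > len(picks) / 2


class TestRhoRecovery:
    @pytest.mark.parametrize("rho_true", [0.0, 0.8])
    def test_reml_argmax_near_truth(self, t_300, rho_true):
        rng = np.random.default_rng(71)
        rhos = []
        for _ in range(12):
            y = model_series(t_300) + make_ar1(rng, len(t_300), rho_true, 0.2)
            fit = fit_harmonic_regression(PixelSeries(y=y, t=t_300), order=2)
            rhos.append(fit.rho)
        tol = 0.15 if rho_true == 0.0 else 0.1
        assert abs(np.mean(rhos) - rho_true) <= tol

    def test_time_origin_shift_by_whole_cycle_preserves_wave(self, t_300):
        rng = np.random.default_rng(9)
        y = model_series(t_300) + make_ar1(rng, len(t_300), 0.4, 0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit0 = fit_harmonic_regression(PixelSeries(y=y, t=t_300), order=2,
                                           knots=(1.0, 2.0))
            fit1 = fit_harmonic_regression(PixelSeries(y=y, t=t_300 + 1.0), order=2,
                                           knots=(2.0, 3.0))
        assert fit1.hrw_amplitude == pytest.approx(fit0.hrw_amplitude, rel=1e-6)
        assert fit1.time_to_trough == pytest.approx(fit0.time_to_trough, abs=1e-6)
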