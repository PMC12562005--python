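"""Distributional machinery: densities, quantiles, moments, tail behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tiwd import (
    InfiniteMomentError,
    LifetimeSample,
    MomentOrder,
    TiwdParams,
    TransformedInverseWeibull,
)

PARAM_GRID = [(0.5, 0.5), (0.5, 1.0), (1.0, 1.0), (2.0, 0.5), (2.0, 3.0),
              (1075.0, 1.19)]


def dist(a, b):
    return TransformedInverseWeibull(a, b)


class TestValidation:
    @pytest.mark.parametrize("alpha,beta", [(0, 1), (-1, 1), (1, 0),
                                            (np.nan, 1), (1, np.inf)])
    def test_rejects_bad_parameters(self, alpha, beta):
        with pytest.raises((ValueError, TypeError)):
            TiwdParams(alpha, beta)

    def test_rejects_nonpositive_observations(self):
        with pytest.raises(ValueError, match="row 2"):
            LifetimeSample([1.0, -3.0, 2.0])
        with pytest.raises(ValueError):
            LifetimeSample([])

    def test_rejects_nonpositive_x(self):
        d = dist(1, 1)
        for fn in (d.pdf, d.cdf, d.reliability_curves):
            with pytest.raises(ValueError):
                fn(-1.0)
            with pytest.raises(ValueError):
                fn(0.0)


class TestDensity:
    def test_closed_forms_at_x_equal_one(self):
        # x=1 forces x^-beta = 1: f(1;1,1) = e^(2-e), F(1;1,b) = e^(1-e)
        assert dist(1, 1).pdf(1.0) == pytest.approx(math.exp(2 - math.e), rel=1e-12)
        assert dist(1, 5).cdf(1.0) == pytest.approx(math.exp(1 - math.e), rel=1e-12)
        assert dist(2, 1).cdf(1.0) == pytest.approx(math.exp(2 * (1 - math.e)), rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(1, 1), (2, 0.5), (1075, 1.19)])
    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0, 10.0])
    def test_pdf_is_cdf_derivative(self, alpha, beta, x):
        d = dist(alpha, beta)
        h = 1e-6 * x
        numeric = (d.cdf(x + h) - d.cdf(x - h)) / (2 * h)
        if numeric == 0.0:
            assert d.pdf(x) < 1e-290
        else:
            assert d.pdf(x) == pytest.approx(numeric, rel=1e-5)

    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_normalization_via_probability_substitution(self, alpha, beta):
        # int f dx = int_0^1 dw after x = rho(w); evaluate the Jacobian
        # identity f(rho(w)) * rho'(w) = 1 pointwise instead of trusting it
        d = dist(alpha, beta)
        w = np.linspace(1e-3, 1 - 1e-3, 201)
        x = d.ppf(w)
        h = 1e-6 * w * (1 - w)
        rho_prime = (d.ppf(w + h) - d.ppf(w - h)) / (2 * h)
        np.testing.assert_allclose(d.pdf(x) * rho_prime, 1.0, rtol=1e-4)

    def test_normalization_direct_quadrature(self):
        val, err = integrate.quad(dist(1, 2).pdf, 0, np.inf, limit=200)
        assert abs(val - 1.0) < 1e-8

    def test_log_pdf_no_overflow_for_tiny_x(self):
        assert np.isfinite(dist(1, 5).log_pdf(1e-6)) or dist(1, 5).log_pdf(1e-6) == -np.inf
        assert dist(1, 2).log_pdf(1e-6) == -np.inf  # density underflows, no NaN


class TestReliability:
    def test_closed_forms(self):
        rc = dist(1, 1).reliability_curves(1.0)
        assert rc.sf == pytest.approx(1 - math.exp(1 - math.e), rel=1e-12)
        assert rc.reversed_hazard == pytest.approx(math.e, rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_definitional_identities(self, alpha, beta):
        d = dist(alpha, beta)
        x = np.geomspace(0.3, 50.0, 50)
        rc = d.reliability_curves(x)
        np.testing.assert_allclose(rc.sf + d.cdf(x), 1.0, rtol=1e-12)
        np.testing.assert_allclose(rc.hazard * rc.sf, d.pdf(x), rtol=1e-12)
        np.testing.assert_allclose(rc.cum_hazard, -np.log(rc.sf), rtol=1e-12)
        np.testing.assert_allclose(rc.reversed_hazard * d.cdf(x), d.pdf(x),
                                   rtol=1e-12)

    def test_hazard_survives_sf_underflow(self):
        # deep left tail: cdf ~ 0, sf ~ 1; and deep right tail: sf ~ 0
        rc = dist(1, 1).reliability_curves(np.array([1e-3, 1e12]))
        assert np.all(np.isfinite(rc.hazard))


class TestQuantile:
    def test_median_closed_form(self):
        # rho(1/2) = 1 / ln(1 - ln(1/2)) for alpha = beta = 1
        expect = 1.0 / math.log(1 - math.log(0.5))
        assert dist(1, 1).ppf(0.5) == pytest.approx(expect, rel=1e-14)
        assert expect == pytest.approx(1.899014098603414, rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 1.0), (2.0, 3.0)])
    def test_quantile_inverts_cdf_closed_form(self, alpha, beta):
        w = math.exp(alpha * (1 - math.e))
        assert dist(alpha, beta).ppf(w) == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_roundtrip(self, alpha, beta):
        d = dist(alpha, beta)
        w = np.array([0.01, 0.25, 0.5, 0.75, 0.99])
        np.testing.assert_allclose(d.cdf(d.ppf(w)), w, atol=1e-10)

    def test_domain_errors(self):
        for w in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                dist(1, 1).ppf(w)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        w1=st.floats(1e-6, 1 - 1e-6),
        w2=st.floats(1e-6, 1 - 1e-6),
        alpha=st.floats(0.05, 50),
        beta=st.floats(0.05, 10),
    )
    def test_strictly_increasing(self, w1, w2, alpha, beta):
        if w1 == w2:
            return
        lo, hi = sorted((w1, w2))
        d = dist(alpha, beta)
        assert d.ppf(lo) < d.ppf(hi)


class TestSampling:
    def test_forced_uniform_stream(self, monkeypatch):
        class FakeRng:
            def uniform(self, size):
                return np.full(size, 0.5)

        monkeypatch.setattr(np.random, "default_rng", lambda seed=None: FakeRng())
        s = dist(1, 1).rvs(1, seed=0)
        assert s.values[0] == pytest.approx(1.0 / math.log(1 - math.log(0.5)))

    def test_seed_determinism(self):
        a = dist(2, 0.5).rvs(1000, seed=7).values
        b = dist(2, 0.5).rvs(1000, seed=7).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, dist(2, 0.5).rvs(1000, seed=8).values)

    def test_ks_self_test_across_seeds(self):
        # at least 19 of 20 consecutive seeds should pass at p > 0.01
        d = dist(1, 1)
        passes = sum(d.ks_self_test(n=100_000, seed=s).pvalue > 0.01
                     for s in range(20))
        assert passes >= 19


class TestMoments:
    def test_finiteness_guard(self):
        with pytest.raises(InfiniteMomentError, match="r < beta"):
            dist(1, 1.5).raw_moment(2)
        with pytest.raises(InfiniteMomentError):
            dist(1, 1.5).raw_moment(MomentOrder(1.5))

    def test_mean_against_monte_carlo(self):
        d = dist(1, 3)
        mu = d.raw_moment(1)
        draws = d.rvs(1_000_000, seed=0).values
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(mu - draws.mean()) < 3 * se

    def test_variance_nonnegative(self):
        for a in (0.5, 1, 2):
            for b in (2.5, 3, 5):
                assert dist(a, b).var() >= 0

    def test_incomplete_moment_limits(self):
        d = dist(1, 3)
        assert d.incomplete_moment(1, 1e-6) < 1e-10
        assert d.incomplete_moment(1, 1e6) == pytest.approx(d.raw_moment(1),
                                                            rel=1e-6)

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0])
    def test_incomplete_moment_against_direct_quadrature(self, x):
        d = dist(1, 3)
        direct, _ = integrate.quad(lambda s: s * d.pdf(s), 0, x, limit=200)
        assert d.incomplete_moment(1, x) == pytest.approx(direct, abs=1e-7)

    def test_incomplete_moment_monotone(self):
        d = dist(1, 3)
        vals = [d.incomplete_moment(1, x) for x in (0.5, 1, 2, 5, 20)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestLorenzBonferroni:
    def test_total_mass_and_definitional(self):
        d = dist(1, 3)
        lb = d.lorenz_bonferroni(1e6)
        assert lb.L == pytest.approx(1.0, abs=1e-6)
        xs = np.array([1.0, 2.0, 4.0])
        lb = d.lorenz_bonferroni(xs)
        np.testing.assert_allclose(lb.B * d.cdf(xs), lb.L, rtol=1e-12)

    def test_lorenz_at_median_against_quadrature(self):
        d = dist(1, 3)
        med = d.ppf(0.5)
        direct, _ = integrate.quad(lambda s: s * d.pdf(s), 0, med, limit=200)
        assert d.lorenz_bonferroni(med).L == pytest.approx(direct / d.mean(),
                                                           rel=1e-6)

    def test_requires_finite_mean(self):
        with pytest.raises(InfiniteMomentError):
            dist(1, 1).lorenz_bonferroni(1.0)


class TestOrderStatistics:
    def test_reductions(self):
        d = dist(1.3, 0.8)
        x = np.geomspace(0.2, 30, 20)
        np.testing.assert_allclose(d.order_statistic_pdf(1, 1, x), d.pdf(x),
                                   rtol=1e-12)
        n = 7
        expect = n * d.pdf(x) * d.cdf(x) ** (n - 1)
        np.testing.assert_allclose(d.order_statistic_pdf(n, n, x), expect,
                                   rtol=1e-10)

    def test_integrates_to_one(self):
        d = dist(1, 1)
        val, _ = integrate.quad(lambda x: d.order_statistic_pdf(3, 5, x),
                                0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_j_out_of_range(self):
        with pytest.raises(ValueError):
            dist(1, 1).order_statistic_pdf(0, 5, 1.0)
        with pytest.raises(ValueError):
            dist(1, 1).order_statistic_pdf(6, 5, 1.0)


class TestMeanResidualLife:
    def test_limit_at_origin_is_mean(self):
        d = dist(1, 3)
        assert d.mean_residual_life(1e-9) == pytest.approx(d.mean(), rel=1e-5)

    def test_definitional_identity(self):
        d = dist(1, 3)
        x = 1.5
        tail, _ = integrate.quad(d.sf, x, np.inf, limit=300,
                                 epsabs=1e-12, epsrel=1e-12)
        assert d.mean_residual_life(x) * d.sf(x) == pytest.approx(tail, abs=1e-8)

    def test_pareto_tail_limit(self):
        # S(x) ~ alpha x^-beta implies m(x) ~ x/(beta-1) far in the tail
        d = dist(1, 3)
        x = 1e3
        assert d.mean_residual_life(x) / (x / (3 - 1)) == pytest.approx(1.0,
                                                                        abs=0.05)

    def test_requires_beta_above_one(self):
        with pytest.raises(InfiniteMomentError):
            dist(1, 1).mean_residual_life(1.0)


class TestShapeMeasures:
    @pytest.mark.parametrize("alpha,beta", PARAM_GRID)
    def test_bowley_bounded(self, alpha, beta):
        s = dist(alpha, beta).shape_measures()
        assert -1 < s.bowley_skewness < 1

    def test_matches_quantile_recomputation(self):
        d = dist(2, 3)
        q = d.ppf
        s = d.shape_measures()
        expect_s = (q(0.75) + q(0.25) - 2 * q(0.5)) / (q(0.75) - q(0.25))
        expect_k = (q(7 / 8) - q(5 / 8) + q(3 / 8) - q(1 / 8)) / (q(6 / 8) - q(2 / 8))
        assert s.bowley_skewness == pytest.approx(expect_s, abs=1e-12)
        assert s.moors_kurtosis == pytest.approx(expect_k, abs=1e-12)

    def test_skewness_decreases_with_beta(self):
        vals = [dist(1, b).shape_measures().bowley_skewness
                for b in (0.5, 1, 2, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestTailDiagnostics:
    def test_exponential_tilt_eventually_increasing(self):
        d = dist(1, 1)
        td = d.tail_diagnostics(0.1, np.geomspace(10, 1e4, 60))
        beyond = td.log_etx_S[td.x_grid > 100]
        assert np.all(np.diff(beyond) > 0)

    @pytest.mark.parametrize("alpha,beta,x", [(1, 1, 1e6), (2, 0.5, 1e12)])
    def test_pareto_ratio_tends_to_one(self, alpha, beta, x):
        # the correction term is O(x^-beta), so the probe point must push
        # x^-beta below the tolerance
        td = dist(alpha, beta).tail_diagnostics(0.1, np.array([x]))
        assert td.pareto_ratio[0] == pytest.approx(1.0, abs=1e-4)

    def test_log_log_slope_recovers_beta(self):
        for alpha, beta in ((1, 1), (2, 0.5)):
            x = np.geomspace(1e4, 1e6, 50)
            logS = np.asarray(dist(alpha, beta).log_sf(x))
            slope = np.polyfit(np.log(x), logS, 1)[0]
            assert slope == pytest.approx(-beta, abs=1e-3)
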