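import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from ppsbayes.exgauss import (
    ExGaussParams,
    exgauss_logpdf,
    exgauss_loglik,
    exgauss_pdf,
    exgauss_rng,
    moment_estimates,
)


def quadrature_convolution(x, params):
    """Independent oracle: numerically convolve Normal(mu, sigma) with
    Exponential(mean tau)."""
    f = lambda u: stats.norm.pdf(u, params.mu, params.sigma) * stats.expon.pdf(
        x - u, scale=params.tau
    )
    lo = params.mu - 10 * params.sigma
    val, _ = integrate.quad(f, lo, x, limit=400)
    return val


class TestDensity:
    params = ExGaussParams(mu=0.3, sigma=0.05, tau=0.2)

    def test_matches_quadrature_convolution(self):
        xs = np.linspace(0.05, 2.0, 100)
        oracle = np.array([quadrature_convolution(x, self.params) for x in xs])
        assert np.max(np.abs(exgauss_pdf(xs, self.params) - oracle)) < 1e-6

    def test_gaussian_limit(self):
        # tau -> 0 collapses to the pure Gaussian component
        xs = np.linspace(-4, 4, 201)
        lim = exgauss_pdf(xs, ExGaussParams(0.0, 1.0, 1e-8))
        assert np.max(np.abs(lim - stats.norm.pdf(xs))) < 1e-4
        assert abs(exgauss_pdf(0.0, ExGaussParams(0.0, 1.0, 1e-8)) - 0.39894) < 1e-4

    def test_integrates_to_one(self):
        xs = np.linspace(-1.0, 4.0, 20001)
        total = np.trapezoid(exgauss_pdf(xs, self.params), xs)
        assert abs(total - 1.0) < 1e-6

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ExGaussParams(0.3, -0.1, 0.2)
        with pytest.raises(ValueError):
            ExGaussParams(0.3, 0.05, 0.0)
        with pytest.raises(ValueError):
            exgauss_logpdf(0.5, 0.3, 0.0, 0.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.floats(-2, 5),
        mu=st.floats(-1, 1),
        sigma=st.floats(0.01, 2),
        tau=st.floats(0.01, 2),
        shift=st.floats(-3, 3),
    )
    def test_location_equivariance(self, x, mu, sigma, tau, shift):
        a = exgauss_logpdf(x, mu, sigma, tau)
        b = exgauss_logpdf(x + shift, mu + shift, sigma, tau)
        assert np.isclose(a, b, rtol=1e-10, atol=1e-10)


class TestSampling:
    params = ExGaussParams(mu=0.3, sigma=0.05, tau=0.2)

    def test_moment_identities(self):
        s = exgauss_rng(self.params, 10**6, seed=1)
        se_mean = np.sqrt(self.params.variance / s.size)
        assert abs(s.mean() - self.params.mean) < 3 * se_mean
        assert abs(s.var() - self.params.variance) < 0.01 * self.params.variance

    def test_ks_against_distribution(self):
        s = exgauss_rng(self.params, 10**5, seed=2)
        # scipy's exponnorm is the same distribution with K = tau/sigma
        K = self.params.tau / self.params.sigma
        stat = stats.kstest(
            s, stats.exponnorm(K, loc=self.params.mu, scale=self.params.sigma).cdf
        ).statistic
        assert stat < 0.005

    def test_reproducible_and_validated(self):
        a = exgauss_rng(self.params, 100, seed=3)
        b = exgauss_rng(self.params, 100, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            exgauss_rng(self.params, 0, seed=3)


class TestLoglik:
    params = ExGaussParams(mu=0.3, sigma=0.05, tau=0.2)

    def test_single_point_and_additivity(self):
        x = 0.45
        single = exgauss_loglik([x], self.params)
        assert np.isclose(
            single, float(exgauss_logpdf(x, 0.3, 0.05, 0.2))
        )
        assert np.isclose(
            exgauss_loglik([x, x], self.params), 2 * single
        )

    def test_grid_maximiser_near_truth(self):
        data = exgauss_rng(self.params, 10**4, seed=4)
        grid = [
            ExGaussParams(m, s, t)
            for m in np.linspace(0.2, 0.4, 9)
            for s in np.linspace(0.02, 0.1, 9)
            for t in np.linspace(0.1, 0.3, 9)
        ]
        best = max(grid, key=lambda p: exgauss_loglik(data, p))
        assert abs(best.mu - 0.3) <= 0.03
        assert abs(best.sigma - 0.05) <= 0.01
        assert abs(best.tau - 0.2) <= 0.03

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            exgauss_loglik([], self.params)


def test_moment_estimates_recover_truth():
    p = ExGaussParams(0.42, 0.035, 0.05)
    s = exgauss_rng(p, 10**5, seed=6)
    est = moment_estimates(s)
    assert abs(est.mu - p.mu) < 0.01
    assert abs(est.tau - p.tau) < 0.015
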