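import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppsbayes.posterior import (
    LogDensityFit,
    classify_bf,
    decide_effect,
    format_bf,
    hdi,
    marginal_cell,
    posterior_mode,
    savage_dickey_bf,
    summarize_effect,
)


def conjugate_bf(xbar, n=20, data_var=1.0, prior_var=5.0):
    """Closed-form normal-normal Savage-Dickey BF10 for a point null."""
    post_var = 1.0 / (1.0 / prior_var + n / data_var)
    post_mean = post_var * n * xbar / data_var
    return stats.norm.pdf(0, 0, np.sqrt(prior_var)) / stats.norm.pdf(
        0, post_mean, np.sqrt(post_var)
    )


class TestSavageDickey:
    def test_prior_draws_give_unit_bf(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0, np.sqrt(5.0), 10**4)
        assert abs(savage_dickey_bf(draws) - 1.0) < 0.1

    def test_conjugate_oracle_moderate_evidence(self):
        # posterior well inside the draw range: single-realisation check
        rng = np.random.default_rng(2)
        for xbar in (0.0, 0.5):
            true = conjugate_bf(xbar)
            post_var = 1.0 / (1.0 / 5.0 + 20.0)
            draws = rng.normal(20 * post_var * xbar, np.sqrt(post_var), 10**4)
            assert abs(savage_dickey_bf(draws) - true) / true < 0.1

    def test_concentrated_draws_capped_display(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(3.0, 0.1, 5000)
        bf = savage_dickey_bf(draws)
        assert bf > 150
        assert format_bf(bf) == ">150"
        assert format_bf(3.2189) == "3.219"

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_bf(np.zeros(500))


class TestLogDensityFit:
    def test_gaussian_tail_extrapolation(self):
        # the BIC-selected fit must extrapolate a normal's quadratic
        # log-density far below the draws (the Savage-Dickey regime)
        rng = np.random.default_rng(4)
        draws = rng.normal(2.0, 0.25, 10**4)
        fit = LogDensityFit(draws)
        assert fit.degree == 2
        lp = fit.logpdf(np.array(0.0))
        true = stats.norm.logpdf(0.0, 2.0, 0.25)
        assert abs(lp - true) < 1.5  # ~9 SD extrapolation, MC-limited

    def test_skewed_density_gets_higher_degree(self):
        rng = np.random.default_rng(5)
        draws = rng.gamma(3.0, 1.0, 10**4)
        fit = LogDensityFit(draws)
        assert fit.degree >= 3


class TestClassifyBf:
    @pytest.mark.parametrize(
        "bf, label",
        [(7.306, "H1"), (53.021, "H1"), (151.0, "H1"),
         (0.179, "H0"), (0.03, "H0"),
         (1.0, "inconclusive"), (4.99, "inconclusive"), (0.21, "inconclusive")],
    )
    def test_thresholds(self, bf, label):
        assert classify_bf(bf) == label

    def test_invalid(self):
        with pytest.raises(ValueError):
            classify_bf(0.0)


class TestHdi:
    def test_standard_normal(self):
        rng = np.random.default_rng(6)
        lo, hi = hdi(rng.normal(0, 1, 10**5))
        assert abs(lo + 1.96) < 0.05
        assert abs(hi - 1.96) < 0.05

    def test_constant_draws(self):
        lo, hi = hdi(np.full(200, 3.7))
        assert lo == hi == 3.7

    def test_uniform_length(self):
        rng = np.random.default_rng(7)
        lo, hi = hdi(rng.uniform(0, 1, 10**5))
        assert abs((hi - lo) - 0.95) < 0.01

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hdi(np.random.default_rng(0).normal(size=200), mass=1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(mass=st.floats(0.5, 0.99), seed=st.integers(0, 100))
    def test_contains_requested_mass(self, mass, seed):
        draws = np.random.default_rng(seed).normal(size=2000)
        lo, hi = hdi(draws, mass=mass)
        frac = np.mean((draws >= lo) & (draws <= hi))
        assert frac >= mass - 1e-9


class TestMode:
    def test_normal_mode(self):
        rng = np.random.default_rng(8)
        assert abs(posterior_mode(rng.normal(2, 1, 10**5)) - 2.0) < 0.05

    def test_exponential_boundary_mode(self):
        rng = np.random.default_rng(9)
        assert posterior_mode(rng.exponential(1.0, 10**5)) < 0.1


class TestMarginalCell:
    def test_zero_contrast_convention(self):
        draws = np.random.default_rng(10).normal(size=(3, 1000))
        mc = marginal_cell(draws, np.zeros(3))
        assert mc.pr_positive == 50.0
        assert mc.decision == "no_decision"

    def test_unit_contrast_identity(self):
        draws = np.random.default_rng(11).normal(size=(3, 1000))
        mc = marginal_cell(draws, [0, 1, 0])
        np.testing.assert_array_equal(mc.draws, draws[1])

    def test_linearity_per_draw(self):
        draws = np.random.default_rng(12).normal(size=(4, 500))
        c1 = np.array([1.0, 0.5, 0, -1])
        c2 = np.array([0, 2.0, -0.5, 1])
        lhs = marginal_cell(draws, c1 + c2).draws
        rhs = marginal_cell(draws, c1).draws + marginal_cell(draws, c2).draws
        np.testing.assert_allclose(lhs, rhs)

    def test_length_mismatch(self):
        draws = np.random.default_rng(13).normal(size=(3, 100))
        with pytest.raises(ValueError):
            marginal_cell(draws, [1, 0])


class TestDecideEffect:
    @pytest.mark.parametrize(
        "pr, decision",
        [(99.99, "effect_positive"), (83.5, "effect_positive"),
         (13.46, "effect_negative"), (1.14, "effect_negative"),
         (16.5, "effect_negative"), (50.0, "no_decision"),
         (83.49, "no_decision"), (65.57, "no_decision")],
    )
    def test_thresholds(self, pr, decision):
        assert decide_effect(pr) == decision

    def test_range_validation(self):
        with pytest.raises(ValueError):
            decide_effect(101.0)


class TestSummarizeEffect:
    def test_summary_structure_and_format(self):
        rng = np.random.default_rng(14)
        chains = rng.normal(0.039, 0.0055, (4, 2500))
        s = summarize_effect(chains, name="cell")
        assert s.hdi_low <= s.mode <= s.hdi_high
        assert s.bf10 > 0
        text = s.formatted(decimals=2, scale=1000.0)
        # the study's "mode {low, high}" reporting shape
        assert "{" in text and "}" in text and "," in text
        left = float(text.split(" ")[0])
        assert abs(left - 39.0) < 3.0

    def test_prior_like_draws_inconclusive(self):
        rng = np.random.default_rng(15)
        chains = rng.normal(0, np.sqrt(5.0), (4, 2500))
        assert summarize_effect(chains).hypothesis == "inconclusive"
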