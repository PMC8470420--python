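import numpy as np
import pandas as pd
import pytest

from ppsbayes import designs
from ppsbayes.coding import GROUP_CODE
from ppsbayes.designs import llcct_frame, simulate_llcct_study
from ppsbayes.models import (
    COVARIATE_TERMS,
    CongruencyModelSpec,
    CovariateModelSpec,
    DataError,
    DegenerateDataError,
    OrdinalModelSpec,
    RobustLinearSpec,
    congruency_ppp,
    fit_congruency_model,
    fit_covariate_model,
    fit_ordinal_model,
    fit_robust_linear,
    participant_ce_summary,
)
from ppsbayes.posterior import hdi, savage_dickey_bf


class TestCongruencyModel:
    def test_returns_all_population_terms(self, small_llcct_fit):
        post, _ = small_llcct_fit
        assert len(post.meta["terms"]) == 12
        n_kept = post.meta["n_iter"] - post.meta["n_warmup"]
        for t in post.meta["terms"]:
            assert post.chains(t).shape == (4, n_kept)
        for extra in ("sigma", "tau", "sd_participant_rt", "sd_ce_space"):
            assert extra in post.names()
            assert np.all(post.flat(extra) > 0)

    def test_residual_parameters_recovered(self, small_llcct_fit):
        post, truth = small_llcct_fit
        assert abs(post.flat("sigma").mean() - truth.residual.sigma) < 0.01
        assert abs(post.flat("tau").mean() - truth.residual.tau) < 0.01

    def test_null_fit_detects_nothing(self, scored_profiles):
        """All true effects zero: no non-intercept effect reaches the
        H1 evidence threshold, and the 95% HDIs cover zero at their
        nominal rate (at most one of eleven may miss by chance)."""
        df = llcct_frame(
            simulate_llcct_study(
                scored_profiles, designs.null_truth(), seed=21,
                conditions=("REAL",), repeats_per_cell=2,
            )
        )
        post = fit_congruency_model(
            df, CongruencyModelSpec(seed=22, iterations=1000, warmup=500)
        )
        misses = 0
        for t in post.meta["terms"]:
            if t == "Intercept":
                continue
            assert savage_dickey_bf(post.flat(t)) < 5, t
            lo, hi = hdi(post.flat(t))
            misses += not (lo <= 0 <= hi)
        assert misses <= 1

    def test_input_validation(self, small_llcct_data):
        df, _ = small_llcct_data
        bad = df.copy()
        bad.loc[bad["rt"].notna().idxmax(), "rt"] = -0.1
        with pytest.raises((DataError, ValueError)):
            fit_congruency_model(bad, CongruencyModelSpec(
                seed=1, iterations=200, warmup=100))
        solo = df[df["participant_id"] == df["participant_id"].iloc[0]]
        with pytest.raises(DataError):
            fit_congruency_model(solo, CongruencyModelSpec(
                seed=1, iterations=200, warmup=100))
        onesided = df[df["congruency"] != "incongruent"]
        with pytest.raises(DataError):
            fit_congruency_model(onesided, CongruencyModelSpec(
                seed=1, iterations=200, warmup=100))

    def test_ppp_self_consistency(self, small_llcct_fit):
        post, _ = small_llcct_fit
        ppp = congruency_ppp(post, n_rep=150, seed=2)
        assert 0.1 < ppp < 0.9


class TestOrdinalModel:
    def _simulate(self, shift, n, seed):
        rng = np.random.default_rng(seed)
        g = np.repeat([0.5, -0.5], n // 2)
        latent = shift * g + rng.logistic(size=n)
        y = np.digitize(latent, [-1.5, -0.5, 0.5, 1.5])
        return y, g[:, None]

    def test_latent_shift_detected(self):
        y, X = self._simulate(1.5, 200, seed=1)
        post = fit_ordinal_model(y, X, OrdinalModelSpec(seed=2),
                                 term_names=["Group"])
        d = post.flat("Group")
        assert np.mean(d > 0) > 0.95
        assert savage_dickey_bf(d) > 5

    def test_null_favoured_in_majority_of_replicates(self):
        wins = 0
        for seed in range(20):
            y, X = self._simulate(0.0, 200, seed=100 + seed)
            post = fit_ordinal_model(
                y, X, OrdinalModelSpec(seed=seed, iterations=1500, warmup=750),
                term_names=["Group"],
            )
            if savage_dickey_bf(post.flat("Group")) < 1 / 5:
                wins += 1
        assert wins > 10

    def test_thresholds_strictly_increasing(self):
        y, X = self._simulate(1.0, 150, seed=3)
        post = fit_ordinal_model(y, X, OrdinalModelSpec(seed=4),
                                 term_names=["Group"])
        cuts = [post.flat(f"threshold_{k}") for k in range(1, 5)]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            assert np.all(lo < hi)

    def test_single_category_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_ordinal_model(np.ones(50), np.zeros((50, 1)))


class TestRobustLinear:
    def test_null_groups_support_h0_in_majority_of_replicates(self):
        # the realised group difference of one 200-sample draw can sit
        # ~1.5 SE out, so the null-support property is asserted over
        # replicates rather than on a single dataset
        g = np.repeat([0.5, -0.5], 100)
        X = np.column_stack([np.ones(200), g])
        wins = 0
        for seed in range(20):
            y = np.random.default_rng(500 + seed).normal(10, 1, 200)
            post = fit_robust_linear(
                y, X, RobustLinearSpec(seed=seed, iterations=1500, warmup=750),
                term_names=["Intercept", "Group"])
            wins += savage_dickey_bf(post.flat("Group")) < 1 / 5
        assert wins > 10

    def test_three_sd_difference_detected(self):
        rng = np.random.default_rng(7)
        g = np.repeat([0.5, -0.5], 100)
        y = rng.normal(10, 1, 200) + 3.0 * g  # 3 residual SDs apart
        X = np.column_stack([np.ones(200), g])
        post = fit_robust_linear(y, X, RobustLinearSpec(seed=8),
                                 term_names=["Intercept", "Group"])
        assert np.mean(post.flat("Group") > 0) > 0.99

    def test_outlier_resistance_vs_gaussian(self):
        rng = np.random.default_rng(9)
        g = np.repeat([0.5, -0.5], 50)
        y = rng.normal(0, 1, 100)
        y_out = y.copy()
        y_out[0] += 40.0
        X = np.column_stack([np.ones(100), g])

        def shift(student_t):
            spec = lambda s: RobustLinearSpec(seed=s, student_t=student_t)
            base = fit_robust_linear(y, X, spec(10), ["I", "Group"])
            pert = fit_robust_linear(y_out, X, spec(10), ["I", "Group"])
            return abs(pert.flat("Group").mean() - base.flat("Group").mean())

        assert shift(student_t=True) < shift(student_t=False)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_robust_linear(np.full(30, 2.0), np.ones((30, 1)))


class TestCovariateModel:
    def _profiles(self, n=60, seed=12):
        return designs.generate_cohort(n=n, n_motor=n // 2, seed=seed)

    def test_twelve_terms(self):
        profiles = self._profiles(20)
        rng = np.random.default_rng(1)
        post = fit_covariate_model(
            rng.normal(0, 0.02, 20), profiles,
            CovariateModelSpec(seed=2, iterations=1000, warmup=500),
        )
        assert post.meta["terms"] == COVARIATE_TERMS
        assert len(COVARIATE_TERMS) == 12

    def test_pure_interaction_recovered(self):
        from ppsbayes.models import covariate_design

        profiles = self._profiles(60)
        X = covariate_design(profiles)
        rng = np.random.default_rng(3)
        ix = COVARIATE_TERMS.index("Group:PSFS-Frequency")
        y = 0.05 * X[:, ix] + rng.normal(0, 0.02, 60)
        post = fit_covariate_model(y, profiles, CovariateModelSpec(seed=4))
        bfs = {t: savage_dickey_bf(post.flat(t)) for t in COVARIATE_TERMS}
        assert bfs["Group:PSFS-Frequency"] > 5
        others = [v for k, v in bfs.items()
                  if k not in ("Group:PSFS-Frequency", "Intercept")]
        assert all(v < 1 for v in others)

    def test_null_effects_covered(self):
        profiles = self._profiles(40, seed=13)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.02, 40)
        post = fit_covariate_model(y, profiles, CovariateModelSpec(seed=6))
        for t in COVARIATE_TERMS:
            lo, hi = hdi(post.flat(t))
            assert lo <= 0 <= hi

    def test_missing_covariate_raises(self, table1):
        # the published demographics table carries no clinical scores
        with pytest.raises(DataError):
            fit_covariate_model(np.zeros(15), table1)


def test_participant_ce_summary(small_llcct_data):
    df, _ = small_llcct_data
    ce = participant_ce_summary(df, timepoint="T1", condition="REAL",
                                cell=("space", "homolateral"))
    assert len(ce) == df["participant_id"].nunique()
    sub = df[(df["timepoint"] == "T1") & (df["space"] == "homolateral")
             & df["rt"].notna()]
    pid = ce.index[0]
    m = sub[sub["participant_id"] == pid].groupby("congruency")["rt"].mean()
    assert np.isclose(ce[pid], m["incongruent"] - m["congruent"])
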