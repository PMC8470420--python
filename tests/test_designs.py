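import numpy as np
import pandas as pd
import pytest

from ppsbayes import designs
from ppsbayes.designs import (
    DesignError,
    ConfigurationError,
    bst_frame,
    clinical_longitudinal,
    default_truth,
    generate_bst_session,
    generate_cohort,
    generate_llcct_block,
    generate_mi_training_session,
    llcct_frame,
    null_truth,
    simulate_bst_rts,
    simulate_llcct_rts,
    tactile_stimulus_profile,
)


class TestLlcctBlock:
    def test_default_counts(self):
        trials = generate_llcct_block("REAL", seed=1)
        assert len(trials) == 162
        kinds = pd.Series([t.trial_kind for t in trials]).value_counts()
        assert kinds["test"] == 128
        assert kinds["catch"] == 18
        assert kinds["false_stim"] == 16

    def test_factorial_balance_and_derivations(self):
        trials = [t for t in generate_llcct_block("VOID", seed=2)
                  if t.trial_kind == "test"]
        cells = pd.Series(
            [(t.tactile_side, t.tactile_pos, t.visual_side, t.visual_pos)
             for t in trials]
        ).value_counts()
        assert len(cells) == 16 and cells.nunique() == 1
        for t in trials:
            assert (t.space == "homolateral") == (t.tactile_side == t.visual_side)
            assert (t.congruency == "congruent") == (t.tactile_pos == t.visual_pos)

    def test_seed_determinism_and_errors(self):
        a = generate_llcct_block("REAL", seed=7)
        b = generate_llcct_block("REAL", seed=7)
        assert a == b
        assert a != generate_llcct_block("REAL", seed=8)
        with pytest.raises(DesignError):
            generate_llcct_block("HALF", seed=1)
        with pytest.raises(DesignError):
            generate_llcct_block("REAL", seed=1, repeats_per_cell=0)


class TestBstSession:
    def test_counts_and_balance(self):
        trials = generate_bst_session(seed=3)
        assert len(trials) == 96
        df = bst_frame(trials)
        per_block = df.groupby("block_index")["congruency"].value_counts()
        assert (per_block == 12).all()

    @pytest.mark.parametrize(
        "order, expected",
        [
            ("Foot-Hand-Hand-Foot", ["foot", "hand", "hand", "foot"]),
            ("Hand-Foot-Foot-Hand", ["hand", "foot", "foot", "hand"]),
        ],
    )
    def test_block_orders(self, order, expected):
        df = bst_frame(generate_bst_session(seed=4, block_order=order))
        got = df.groupby("block_index")["background"].first().tolist()
        assert got == expected

    def test_colour_side_congruency_rule(self):
        for t in generate_bst_session(seed=5):
            expected = (
                "congruent"
                if (t.circle_colour == "red") == (t.background_side == "left")
                else "incongruent"
            )
            assert t.congruency == expected

    def test_unknown_order_raises(self):
        with pytest.raises(DesignError):
            generate_bst_session(seed=1, block_order="Hand-Hand-Foot-Foot")


def test_tactile_stimulus_profile():
    prof = tactile_stimulus_profile()
    assert prof["total_span_ms"] == 250
    assert prof["visual_lead_ms"] == 30
    segs = prof["vibration_segments_ms"]
    assert len(segs) == 3 and all(d == 50 for _, d in segs)
    gaps = [segs[i + 1][0] - (segs[i][0] + segs[i][1]) for i in range(2)]
    assert gaps == [50, 50]


def test_mi_training_session():
    items = generate_mi_training_session()
    assert len(items) == 24
    counts = pd.Series(items).value_counts()
    assert len(counts) == 12 and (counts == 2).all()
    cats = pd.Series([c for c, _ in items]).value_counts()
    assert cats.to_dict() == {"upper": 8, "lower": 8, "whole": 8}


class TestCohort:
    def test_defaults(self):
        cohort = generate_cohort(seed=1)
        assert len(cohort) == 15
        groups = pd.Series([p.group for p in cohort]).value_counts()
        assert groups["Motor"] == 8 and groups["Motor+MI"] == 7
        for p in cohort:
            assert p.n_sessions >= 8
            assert p.age_years >= 18
            assert p.lesion_onset_years >= 1
            assert np.isclose(
                p.vmiq2_avg, np.mean([p.vmiq2_1pp, p.vmiq2_3pp, p.vmiq2_kin])
            )

    def test_determinism_and_errors(self):
        assert generate_cohort(seed=2) == generate_cohort(seed=2)
        with pytest.raises(DesignError):
            generate_cohort(n=5, n_motor=5, seed=1)
        with pytest.raises(DesignError):
            generate_cohort(n=1, n_motor=0, seed=1)

    def test_table1_fixture(self, table1):
        assert len(table1) == 15
        groups = pd.Series([p.group for p in table1]).value_counts()
        assert groups.to_dict() == {"Motor": 8, "Motor+MI": 7}
        assert all(p.n_sessions >= 8 for p in table1)


class TestRtSimulation:
    def test_null_truth_gives_zero_congruency_effect(self, scored_profiles):
        df = llcct_frame(
            designs.simulate_llcct_study(
                scored_profiles, null_truth(), seed=1, conditions=("REAL",),
                repeats_per_cell=12,
            )
        )
        sub = df[df["rt"].notna()]
        means = sub.groupby("congruency")["rt"].mean()
        assert abs(means["incongruent"] - means["congruent"]) < 0.005

    def test_effect_truth_recovered_empirically(self, scored_profiles):
        # Motor+MI / T1: homolateral 40 ms vs bilateral 10 ms -> 30 ms gap
        truth = default_truth()
        mi = [p for p in scored_profiles if p.group == "Motor+MI"]
        df = llcct_frame(
            designs.simulate_llcct_study(
                mi, truth, seed=2, conditions=("REAL",), repeats_per_cell=312,
            )
        )
        assert len(df) > 1e5
        sub = df[(df["timepoint"] == "T1") & df["rt"].notna()]
        ce = sub.groupby(["space", "congruency"])["rt"].mean().unstack()
        ce = ce["incongruent"] - ce["congruent"]
        gap = ce["homolateral"] - ce["bilateral"]
        assert abs(gap - 0.030) < 0.006

    def test_rt_mean_matches_exgaussian_identity(self, scored_profiles):
        truth = null_truth()
        df = llcct_frame(
            designs.simulate_llcct_study(
                scored_profiles, truth, seed=3, conditions=("REAL",),
                repeats_per_cell=12,
            )
        )
        grand = df["rt"].dropna().mean()
        assert abs(grand - (truth.residual.mu + truth.residual.tau)) < 0.015

    def test_catch_trials_carry_no_rt(self, scored_profiles):
        trials = generate_llcct_block(
            "REAL", seed=4, participant_id=scored_profiles[0].id,
            group=scored_profiles[0].group,
        )
        out = simulate_llcct_rts(trials, scored_profiles, default_truth(), seed=5)
        for t in out:
            if t.trial_kind != "test":
                assert t.rt is None
            elif not t.response_ok:
                assert t.rt is None
            else:
                assert t.rt > 0

    def test_missing_truth_cell_raises(self, scored_profiles):
        truth = default_truth()
        broken = dict(truth.llcct_ce)
        broken.pop(("Motor", "T0", "homolateral"))
        bad = designs.TrueEffectMap(
            llcct_ce=broken, llcct_ce_void=truth.llcct_ce_void,
            bst_ce=truth.bst_ce,
        )
        trials = generate_llcct_block(
            "REAL", seed=6, participant_id=scored_profiles[0].id,
            group="Motor", timepoint="T0",
        )
        with pytest.raises(ConfigurationError):
            simulate_llcct_rts(trials, scored_profiles, bad, seed=7)

    def test_bst_rt_cap(self, scored_profiles):
        trials = designs.simulate_bst_study(
            scored_profiles, default_truth(), seed=8
        )
        for t in trials:
            if t.timed_out:
                assert t.rt is None
            elif t.rt is not None:
                assert 0 < t.rt <= 1.0


def test_clinical_longitudinal_stability(scored_profiles):
    df = clinical_longitudinal(scored_profiles, seed=1)
    assert len(df) == 3 * len(scored_profiles)
    t0 = df[df["timepoint"] == "T0"].set_index("participant_id")
    for p in scored_profiles:
        assert t0.loc[p.id, "psfs_frequency"] == p.psfs_frequency
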