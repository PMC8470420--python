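"""Synthetic study designs: visuo-tactile (LLCCT) and body-sidedness (BST)
tasks, motor-imagery training sessions, and a Table-1-like SCI cohort.

The generators reproduce the two experimental paradigms of the study this
package reanalyses:

* LLCCT — Lower Limbs Crossmodal Congruency Task.  Vibrotactile targets at
  the top/bottom of handheld stimulators with visual LED distractors near
  the feet; the incongruent-minus-congruent RT cost (Congruency Effect) is
  larger when the distractor is homolateral to the touched hand, indexing
  peripersonal space.  One block = 162 trials (128 factorial test trials +
  18 catch + 16 false-stimulation trials by default), run in a REAL
  (feet in the apparatus) and a VOID (feet hidden) condition at each of
  three timepoints T0/T1/T2.

* BST — Body Sidedness Task, a Simon-like task: red/blue circle over a
  left/right hand or foot photograph; colour-side mapping conflicts define
  congruency.  One session = 4 blocks x 24 trials = 96 trials, responses
  within 1 s.

Reaction times are simulated from an ex-Gaussian whose Gaussian mean
shifts on incongruent trials by the cell's true Congruency Effect plus
participant-level varying effects — the same generative structure the
hierarchical model assumes, so ground-truth recovery is well-defined.
Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exgauss import ExGaussParams

GROUPS = ("Motor", "Motor+MI")
TIMEPOINTS = ("T0", "T1", "T2")
SPACES = ("homolateral", "bilateral")
BACKGROUNDS = ("hand", "foot")

#: BST block orders used in the study (background of blocks 1..4).
BST_BLOCK_ORDERS = {
    "Foot-Hand-Hand-Foot": ("foot", "hand", "hand", "foot"),
    "Hand-Foot-Foot-Hand": ("hand", "foot", "foot", "hand"),
}


class DesignError(ValueError):
    """Invalid task-design configuration."""


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------


@dataclass
class LlcctTrial:
    participant_id: str
    group: str
    timepoint: str
    condition: str  # REAL | VOID
    trial_kind: str  # test | catch | false_stim
    tactile_side: str | None
    tactile_pos: str | None
    visual_side: str | None
    visual_pos: str | None
    rt: float | None = None
    response_ok: bool = True

    @property
    def space(self) -> str | None:
        """homolateral iff tactile and visual stimuli share a body side."""
        if self.trial_kind != "test":
            return None
        return "homolateral" if self.tactile_side == self.visual_side else "bilateral"

    @property
    def congruency(self) -> str | None:
        """congruent iff tactile and visual positions match (top/top or bottom/bottom)."""
        if self.trial_kind != "test":
            return None
        return "congruent" if self.tactile_pos == self.visual_pos else "incongruent"


@dataclass
class BstTrial:
    participant_id: str
    group: str
    timepoint: str
    block_index: int  # 1..4
    background: str  # hand | foot
    background_side: str  # left | right
    circle_colour: str  # red | blue
    rt: float | None = None
    accurate: bool = True
    timed_out: bool = False

    @property
    def congruency(self) -> str:
        """congruent iff colour maps to the depicted side (red-left, blue-right)."""
        cong = (self.circle_colour == "red" and self.background_side == "left") or (
            self.circle_colour == "blue" and self.background_side == "right"
        )
        return "congruent" if cong else "incongruent"


@dataclass
class ParticipantProfile:
    id: str
    age_years: float
    lesion_onset_years: float
    n_sessions: int
    nli_label: str
    ais: str
    group: str
    motor_modality: str
    gender: str
    psfs_frequency: int | None = None
    psfs_intensity: int | None = None
    mas: int | None = None
    mrc_movements: tuple[int, ...] | None = None
    vmiq2_1pp: int | None = None
    vmiq2_3pp: int | None = None
    vmiq2_kin: int | None = None

    @property
    def mrc(self) -> int | None:
        """Single ordinal MRC summary: the worst (minimum) movement score."""
        return None if self.mrc_movements is None else int(min(self.mrc_movements))

    @property
    def vmiq2_avg(self) -> float | None:
        vals = (self.vmiq2_1pp, self.vmiq2_3pp, self.vmiq2_kin)
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# ground truth for simulation
# ---------------------------------------------------------------------------


@dataclass
class TrueEffectMap:
    """Ground-truth Congruency Effects and noise structure for simulation.

    ``llcct_ce`` maps (group, timepoint, space) -> CE in seconds for the
    REAL condition; ``llcct_ce_void`` the same for the control (VOID)
    condition; ``bst_ce`` maps (group, timepoint, background).
    Participant-level SDs give the scale of varying intercepts (on the
    RT baseline) and varying CE effects (intercept / time-linear /
    time-quadratic / space-or-background slopes).
    """

    llcct_ce: Mapping[tuple[str, str, str], float]
    llcct_ce_void: Mapping[tuple[str, str, str], float]
    bst_ce: Mapping[tuple[str, str, str], float]
    residual: ExGaussParams = ExGaussParams(mu=0.42, sigma=0.035, tau=0.050)
    bst_residual: ExGaussParams = ExGaussParams(mu=0.38, sigma=0.035, tau=0.050)
    sd_intercept: float = 0.040
    sd_ce: tuple[float, float, float, float] = (0.008, 0.003, 0.003, 0.004)
    error_rate: float = 0.02


def default_truth() -> TrueEffectMap:
    """Study-condition ground truth used throughout tests and examples.

    The REAL condition carries a peripersonal-space signature only in the
    Motor+MI group at T1 (homolateral CE 40 ms vs bilateral 10 ms); every
    other cell's homolateral/bilateral gap is at most 5 ms, with overall
    CE magnitudes loosely matching the study's reported cell modes.  The
    VOID control has no homolateral/bilateral differences.  The BST truth
    mimics the delayed foot-representation recovery (foot CE emerging at
    T2, hand CE stable).
    """
    llcct = {
        ("Motor+MI", "T0", "homolateral"): -0.006,
        ("Motor+MI", "T0", "bilateral"): -0.002,
        ("Motor+MI", "T1", "homolateral"): 0.040,
        ("Motor+MI", "T1", "bilateral"): 0.010,
        ("Motor+MI", "T2", "homolateral"): 0.016,
        ("Motor+MI", "T2", "bilateral"): 0.020,
        ("Motor", "T0", "homolateral"): -0.008,
        ("Motor", "T0", "bilateral"): -0.004,
        ("Motor", "T1", "homolateral"): 0.016,
        ("Motor", "T1", "bilateral"): 0.020,
        ("Motor", "T2", "homolateral"): -0.002,
        ("Motor", "T2", "bilateral"): 0.002,
    }
    void = {
        (g, t, s): 0.005
        for g in GROUPS
        for t in TIMEPOINTS
        for s in SPACES
    }
    bst = {
        ("Motor+MI", "T0", "hand"): 0.004,
        ("Motor+MI", "T1", "hand"): 0.003,
        ("Motor+MI", "T2", "hand"): 0.002,
        ("Motor+MI", "T0", "foot"): 0.000,
        ("Motor+MI", "T1", "foot"): -0.001,
        ("Motor+MI", "T2", "foot"): 0.010,
        ("Motor", "T0", "hand"): 0.005,
        ("Motor", "T1", "hand"): 0.003,
        ("Motor", "T2", "hand"): 0.002,
        ("Motor", "T0", "foot"): 0.000,
        ("Motor", "T1", "foot"): 0.000,
        ("Motor", "T2", "foot"): 0.008,
    }
    return TrueEffectMap(llcct_ce=llcct, llcct_ce_void=void, bst_ce=bst)


def null_truth() -> TrueEffectMap:
    """All Congruency Effects exactly zero (null-calibration conditions)."""
    zeros = {(g, t, s): 0.0 for g in GROUPS for t in TIMEPOINTS for s in SPACES}
    bst_zeros = {(g, t, b): 0.0 for g in GROUPS for t in TIMEPOINTS for b in BACKGROUNDS}
    return TrueEffectMap(llcct_ce=zeros, llcct_ce_void=dict(zeros), bst_ce=bst_zeros)


# ---------------------------------------------------------------------------
# design generators
# ---------------------------------------------------------------------------


def generate_llcct_block(
    condition: str,
    seed,
    repeats_per_cell: int = 8,
    n_catch: int = 18,
    n_false: int = 16,
    participant_id: str = "P",
    group: str = "Motor",
    timepoint: str = "T0",
) -> list[LlcctTrial]:
    """One LLCCT block: a balanced 2^4 factorial of test trials plus
    catch (green-LED) and false-stimulation trials, order randomised by
    seed.  Defaults give the study's 162-trial block.
    """
    if condition not in ("REAL", "VOID"):
        raise DesignError(f"condition must be REAL or VOID, got {condition!r}")
    if repeats_per_cell < 1:
        raise DesignError("repeats_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[LlcctTrial] = []
    for _ in range(repeats_per_cell):
        for ts in ("left", "right"):
            for tp in ("upper", "lower"):
                for vs in ("left", "right"):
                    for vp in ("upper", "lower"):
                        trials.append(
                            LlcctTrial(
                                participant_id,
                                group,
                                timepoint,
                                condition,
                                "test",
                                ts,
                                tp,
                                vs,
                                vp,
                            )
                        )
    for _ in range(n_catch):
        trials.append(
            LlcctTrial(participant_id, group, timepoint, condition, "catch",
                       None, None, None, None)
        )
    for _ in range(n_false):
        side = rng.choice(["left", "right"])
        pos = rng.choice(["upper", "lower"])
        trials.append(
            LlcctTrial(participant_id, group, timepoint, condition, "false_stim",
                       None, None, side, pos)
        )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def generate_bst_session(
    seed,
    block_order: str = "Foot-Hand-Hand-Foot",
    repeats: int = 6,
    participant_id: str = "P",
    group: str = "Motor",
    timepoint: str = "T0",
) -> list[BstTrial]:
    """One BST session: 4 background blocks x (2 sides x 2 colours x
    ``repeats``) trials, 96 total by default; half of each block is
    congruent by construction.
    """
    if block_order not in BST_BLOCK_ORDERS:
        raise DesignError(
            f"unknown block order {block_order!r}; "
            f"expected one of {sorted(BST_BLOCK_ORDERS)}"
        )
    rng = np.random.default_rng(seed)
    trials: list[BstTrial] = []
    for b, background in enumerate(BST_BLOCK_ORDERS[block_order], start=1):
        block: list[BstTrial] = []
        for _ in range(repeats):
            for side in ("left", "right"):
                for colour in ("red", "blue"):
                    block.append(
                        BstTrial(participant_id, group, timepoint, b,
                                 background, side, colour)
                    )
        order = rng.permutation(len(block))
        trials.extend(block[i] for i in order)
    return trials


def tactile_stimulus_profile() -> dict:
    """Timing of one tactile stimulus: three 50 ms vibrations separated
    by 50 ms gaps (250 ms total), with the visual distractor LED leading
    the tactile onset by 30 ms."""
    segments = [(0, 50), (100, 50), (200, 50)]
    return {
        "vibration_segments_ms": segments,
        "total_span_ms": segments[-1][0] + segments[-1][1],
        "visual_lead_ms": 30,
    }


MI_ACTIONS = {
    "upper": ("reach for a glass", "comb hair", "throw a ball", "turn a key"),
    "lower": ("kick a ball", "climb a step", "tap the foot", "pedal"),
    "whole": ("stand up", "swim", "jump", "bow"),
}


def generate_mi_training_session() -> list[tuple[str, str]]:
    """One motor-imagery training session: 12 distinct actions (4 upper
    limb, 4 lower limb, 4 whole body), each imagined twice -> 24 items."""
    items = [(cat, act) for cat, acts in MI_ACTIONS.items() for act in acts]
    return items + items


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_NLI_LABELS = (
    [f"C{i}" for i in range(1, 9)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
)


def table1_cohort() -> list[ParticipantProfile]:
    """The 15 study participants, verbatim from the published cohort table
    (clinical demographics only; scale scores are not printed there)."""
    with importlib.resources.files("ppsbayes.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        ParticipantProfile(
            id=r.id,
            age_years=float(r.age_years),
            lesion_onset_years=float(r.lesion_onset_years),
            n_sessions=int(r.n_sessions),
            nli_label=r.nli_label,
            ais=r.ais,
            group=r.group,
            motor_modality=r.motor_modality,
            gender=r.gender,
        )
        for r in df.itertuples()
    ]


def generate_cohort(n: int = 15, n_motor: int = 8, seed=0) -> list[ParticipantProfile]:
    """Synthetic cohort with the study's structure: ``n_motor`` Motor and
    ``n - n_motor`` Motor+MI participants, chronic adult-onset lesions,
    >= 8 rehabilitation sessions, mostly thoracic complete (AIS-A)
    lesions, plus clinical-scale scores drawn from realistic categorical
    distributions."""
    if n < 2:
        raise DesignError("n must be >= 2")
    if n_motor >= n:
        raise DesignError("n_motor must be < n")
    rng = np.random.default_rng(seed)
    groups = ["Motor"] * n_motor + ["Motor+MI"] * (n - n_motor)
    profiles = []
    for i, grp in enumerate(groups, start=1):
        age = float(np.round(rng.uniform(25, 70), 0))
        onset = float(np.round(rng.uniform(1, min(age - 18, 35)), 2))
        # lesion levels: mostly thoracic, a few cervical/lumbar
        nli = rng.choice(_NLI_LABELS[4:8] + _NLI_LABELS[8:20] * 4 + _NLI_LABELS[20:22])
        ais = rng.choice(["A", "A", "A", "A", "C", "D"])
        profiles.append(
            ParticipantProfile(
                id=f"Synth{i:02d}",
                age_years=age,
                lesion_onset_years=onset,
                n_sessions=int(rng.integers(8, 11)),
                nli_label=str(nli),
                ais=str(ais),
                group=grp,
                motor_modality=str(rng.choice(["EKSO", "Mobilisation"])),
                gender=str(rng.choice(["M", "M", "M", "M", "M", "M", "F"])),
                psfs_frequency=int(rng.choice(5, p=[0.25, 0.3, 0.2, 0.15, 0.1])),
                psfs_intensity=int(rng.choice(4, p=[0.3, 0.35, 0.25, 0.1])),
                mas=int(rng.choice(5, p=[0.3, 0.3, 0.2, 0.15, 0.05])),
                mrc_movements=tuple(
                    int(v) for v in rng.choice(4, size=6, p=[0.35, 0.35, 0.2, 0.1])
                ),
                vmiq2_1pp=int(rng.integers(24, 121)),
                vmiq2_3pp=int(rng.integers(24, 121)),
                vmiq2_kin=int(rng.integers(24, 121)),
            )
        )
    return profiles


def with_clinical_scores(profiles: Sequence[ParticipantProfile], seed=0
                         ) -> list[ParticipantProfile]:
    """Fill missing clinical-scale scores on an existing cohort (e.g. the
    published demographics table) with synthetic draws."""
    rng = np.random.default_rng(seed)
    out = []
    for p in profiles:
        out.append(
            replace(
                p,
                psfs_frequency=(p.psfs_frequency if p.psfs_frequency is not None
                                else int(rng.choice(5, p=[0.25, 0.3, 0.2, 0.15, 0.1]))),
                psfs_intensity=(p.psfs_intensity if p.psfs_intensity is not None
                                else int(rng.choice(4, p=[0.3, 0.35, 0.25, 0.1]))),
                mas=p.mas if p.mas is not None else int(rng.choice(5)),
                mrc_movements=(p.mrc_movements if p.mrc_movements is not None else
                               tuple(int(v) for v in rng.choice(4, size=6))),
                vmiq2_1pp=(p.vmiq2_1pp if p.vmiq2_1pp is not None
                           else int(rng.integers(24, 121))),
                vmiq2_3pp=(p.vmiq2_3pp if p.vmiq2_3pp is not None
                           else int(rng.integers(24, 121))),
                vmiq2_kin=(p.vmiq2_kin if p.vmiq2_kin is not None
                           else int(rng.integers(24, 121))),
            )
        )
    return out


def clinical_longitudinal(
    profiles: Sequence[ParticipantProfile], seed=0, stability: float = 0.85
) -> pd.DataFrame:
    """Clinical-scale scores at the three assessments.

    Emulates the study's finding that clinical variables are stable over
    the training period: each follow-up score equals the baseline score
    with probability ``stability``, otherwise it moves one ordinal step
    (clipped to the scale range).
    """
    rng = np.random.default_rng(seed)
    ranges = {"psfs_frequency": (0, 4), "psfs_intensity": (0, 3),
              "mas": (0, 4), "mrc": (0, 5)}
    rows = []
    for p in profiles:
        base = {"psfs_frequency": p.psfs_frequency,
                "psfs_intensity": p.psfs_intensity,
                "mas": p.mas, "mrc": p.mrc}
        if any(v is None for v in base.values()):
            raise ConfigurationError(f"profile {p.id} lacks clinical scores")
        for tp in TIMEPOINTS:
            row = {"participant_id": p.id, "group": p.group, "timepoint": tp}
            for scale, (lo, hi) in ranges.items():
                v = base[scale]
                if tp != "T0" and rng.random() > stability:
                    v = int(np.clip(v + rng.choice([-1, 1]), lo, hi))
                row[scale] = v
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RT simulation
# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    """Missing or inconsistent simulation configuration."""


def _participant_effects(profiles, truth, rng):
    """Draw per-participant varying effects: RT-baseline intercept and
    CE-scale (intercept, time-linear, time-quadratic, space/background)
    deviations."""
    eff = {}
    for p in profiles:
        eff[p.id] = (
            rng.normal(0.0, truth.sd_intercept),
            rng.normal(0.0, np.asarray(truth.sd_ce)),
        )
    return eff


_TIME_LIN = {"T0": -1.0, "T1": 0.0, "T2": 1.0}
_TIME_QUAD = {"T0": 1.0, "T1": -2.0, "T2": 1.0}


def simulate_llcct_rts(
    trials: Iterable[LlcctTrial],
    profiles: Sequence[ParticipantProfile],
    truth: TrueEffectMap,
    seed,
    return_effects: bool = False,
) -> list[LlcctTrial]:
    """Fill RTs on LLCCT trials from the generative ex-Gaussian model.

    mu = mu_base + participant intercept + [incongruent] * CE(cell),
    where CE(cell) = true cell effect + participant-level contributions
    from the varying intercept and time/space slopes.  Catch and
    false-stimulation trials carry no RT; a ``truth.error_rate``
    fraction of test trials is flagged as response errors (no RT).

    With ``return_effects`` the drawn participant effects are returned
    alongside the trials (id -> (intercept, [ce-intercept, time-linear,
    time-quadratic, space] deviations)), so recovery tests can compare
    estimates against the cohort-realised generating values.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in profiles}
    eff = _participant_effects(profiles, truth, rng)
    out = []
    for t in trials:
        if t.participant_id not in by_id:
            raise ConfigurationError(f"unknown participant {t.participant_id!r}")
        if t.trial_kind != "test":
            out.append(replace(t, rt=None, response_ok=True))
            continue
        if rng.random() < truth.error_rate:
            out.append(replace(t, rt=None, response_ok=False))
            continue
        ce_map = truth.llcct_ce if t.condition == "REAL" else truth.llcct_ce_void
        key = (t.group, t.timepoint, t.space)
        if key not in ce_map:
            raise ConfigurationError(f"missing truth cell {key}")
        a_p, u_p = eff[t.participant_id]
        space_code = 0.5 if t.space == "homolateral" else -0.5
        ce = (
            ce_map[key]
            + u_p[0]
            + u_p[1] * _TIME_LIN[t.timepoint]
            + u_p[2] * _TIME_QUAD[t.timepoint]
            + u_p[3] * space_code
        )
        c = 1.0 if t.congruency == "incongruent" else 0.0
        mu = truth.residual.mu + a_p + c * ce
        rt = rng.normal(mu, truth.residual.sigma) + rng.exponential(truth.residual.tau)
        out.append(replace(t, rt=float(max(rt, 1e-3)), response_ok=True))
    if return_effects:
        return out, eff
    return out


def simulate_bst_rts(
    trials: Iterable[BstTrial],
    profiles: Sequence[ParticipantProfile],
    truth: TrueEffectMap,
    seed,
) -> list[BstTrial]:
    """Fill RTs on BST trials; responses slower than 1 s are timed out
    (no RT recorded), matching the task's response window."""
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in profiles}
    eff = _participant_effects(profiles, truth, rng)
    out = []
    for t in trials:
        if t.participant_id not in by_id:
            raise ConfigurationError(f"unknown participant {t.participant_id!r}")
        key = (t.group, t.timepoint, t.background)
        if key not in truth.bst_ce:
            raise ConfigurationError(f"missing truth cell {key}")
        a_p, u_p = eff[t.participant_id]
        bg_code = 0.5 if t.background == "hand" else -0.5
        ce = (
            truth.bst_ce[key]
            + u_p[0]
            + u_p[1] * _TIME_LIN[t.timepoint]
            + u_p[2] * _TIME_QUAD[t.timepoint]
            + u_p[3] * bg_code
        )
        c = 1.0 if t.congruency == "incongruent" else 0.0
        mu = truth.bst_residual.mu + a_p + c * ce
        rt = rng.normal(mu, truth.bst_residual.sigma) + rng.exponential(
            truth.bst_residual.tau
        )
        if rt > 1.0:
            out.append(replace(t, rt=None, accurate=False, timed_out=True))
        elif rng.random() < truth.error_rate:
            out.append(replace(t, rt=None, accurate=False, timed_out=False))
        else:
            out.append(replace(t, rt=float(max(rt, 1e-3)), accurate=True,
                               timed_out=False))
    return out


# ---------------------------------------------------------------------------
# whole-study simulation and tabular views
# ---------------------------------------------------------------------------


def simulate_llcct_study(
    profiles: Sequence[ParticipantProfile],
    truth: TrueEffectMap,
    seed,
    conditions: Sequence[str] = ("REAL", "VOID"),
    repeats_per_cell: int = 8,
    return_effects: bool = False,
) -> list[LlcctTrial]:
    """Simulate the full LLCCT dataset: every participant x timepoint x
    condition block, with RTs (optionally also the realised participant
    effects; see ``simulate_llcct_rts``)."""
    rng = np.random.default_rng(seed)
    trials: list[LlcctTrial] = []
    for p in profiles:
        for tp in TIMEPOINTS:
            for cond in conditions:
                trials.extend(
                    generate_llcct_block(
                        cond,
                        rng.integers(2**31),
                        repeats_per_cell=repeats_per_cell,
                        participant_id=p.id,
                        group=p.group,
                        timepoint=tp,
                    )
                )
    return simulate_llcct_rts(
        trials, profiles, truth, rng.integers(2**31),
        return_effects=return_effects,
    )


def simulate_bst_study(
    profiles: Sequence[ParticipantProfile],
    truth: TrueEffectMap,
    seed,
    repeats: int = 6,
) -> list[BstTrial]:
    """Simulate the full BST dataset, counterbalancing block order across
    participants."""
    rng = np.random.default_rng(seed)
    orders = list(BST_BLOCK_ORDERS)
    trials: list[BstTrial] = []
    for i, p in enumerate(profiles):
        for tp in TIMEPOINTS:
            trials.extend(
                generate_bst_session(
                    rng.integers(2**31),
                    block_order=orders[i % 2],
                    repeats=repeats,
                    participant_id=p.id,
                    group=p.group,
                    timepoint=tp,
                )
            )
    return simulate_bst_rts(trials, profiles, truth, rng.integers(2**31))


def llcct_frame(trials: Iterable[LlcctTrial]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": t.participant_id,
            "group": t.group,
            "timepoint": t.timepoint,
            "condition": t.condition,
            "trial_kind": t.trial_kind,
            "tactile_side": t.tactile_side,
            "tactile_pos": t.tactile_pos,
            "visual_side": t.visual_side,
            "visual_pos": t.visual_pos,
            "space": t.space,
            "congruency": t.congruency,
            "rt": t.rt,
            "response_ok": t.response_ok,
        }
        for t in trials
    ]
    return pd.DataFrame(rows)


def bst_frame(trials: Iterable[BstTrial]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": t.participant_id,
            "group": t.group,
            "timepoint": t.timepoint,
            "block_index": t.block_index,
            "background": t.background,
            "background_side": t.background_side,
            "circle_colour": t.circle_colour,
            "congruency": t.congruency,
            "rt": t.rt,
            "accurate": t.accurate,
            "timed_out": t.timed_out,
        }
        for t in trials
    ]
    return pd.DataFrame(rows)


def cohort_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.id,
                "age_years": p.age_years,
                "lesion_onset_years": p.lesion_onset_years,
                "n_sessions": p.n_sessions,
                "nli_label": p.nli_label,
                "ais": p.ais,
                "group": p.group,
                "motor_modality": p.motor_modality,
                "gender": p.gender,
                "psfs_frequency": p.psfs_frequency,
                "psfs_intensity": p.psfs_intensity,
                "mas": p.mas,
                "mrc": p.mrc,
                "mrc_movements": (";".join(map(str, p.mrc_movements))
                                  if p.mrc_movements else None),
                "vmiq2_1pp": p.vmiq2_1pp,
                "vmiq2_3pp": p.vmiq2_3pp,
                "vmiq2_kin": p.vmiq2_kin,
                "vmiq2_avg": p.vmiq2_avg,
            }
        )
    return pd.DataFrame(rows)
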