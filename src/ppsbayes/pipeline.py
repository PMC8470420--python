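"""End-to-end orchestration of the study's analyses.

``run_pipeline`` executes, in order: the clinical-scale comparability
models, the visuo-tactile (LLCCT) congruency model for the REAL and
VOID conditions with marginal-posterior contrasts, the body-sidedness
(BST) model, and the two T1 covariate models.  Every stage produces an
effect table in the study's reporting layout (mode, 95% HDI, n_eff,
R-hat, BF10, hypothesis), carries its convergence diagnostics, and is
reproducible from the run configuration and seeds.

Models run in seconds; tables display reaction-time effects in
milliseconds (conversion at render time only), rounded to 3 decimals
for posterior summaries and 2 for descriptives.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import coding, designs, models, posterior
from .designs import ParticipantProfile, TrueEffectMap
from .diagnostics import diagnose
from .models import (
    CongruencyModelSpec,
    CovariateModelSpec,
    OrdinalModelSpec,
    RobustLinearSpec,
    congruency_ppp,
    fit_congruency_model,
    fit_covariate_model,
    fit_ordinal_model,
    fit_robust_linear,
    participant_ce_summary,
)
from .posterior import format_bf, marginal_cell, summarize_effect
from .sampler import PosteriorDraws


class DataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# descriptive statistics (cohort table)
# ---------------------------------------------------------------------------

_NUMERIC_COLS = ("age_years", "lesion_onset_years", "n_sessions")
_CATEGORICAL_COLS = ("nli_label", "ais", "group", "motor_modality", "gender")


@dataclass
class CohortSummary:
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    counts: dict[str, dict[str, int]]


def descriptive_stats(profiles: Sequence[ParticipantProfile]) -> CohortSummary:
    """Cohort descriptives in the published table's conventions: means
    rounded to 2 decimals, SDs with the n divisor (population SD), and
    level counts for categorical columns."""
    if not profiles:
        raise DataError("empty cohort")
    df = designs.cohort_frame(profiles)
    means = {c: round(float(df[c].mean()), 2) for c in _NUMERIC_COLS}
    sds = {c: round(float(df[c].std(ddof=0)), 2) for c in _NUMERIC_COLS}
    counts = {
        c: df[c].value_counts().to_dict() for c in _CATEGORICAL_COLS
    }
    return CohortSummary(n=len(df), means=means, sds=sds, counts=counts)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

LLCCT_COLUMNS = [
    "participant_id", "group", "timepoint", "condition", "trial_kind",
    "tactile_side", "tactile_pos", "visual_side", "visual_pos",
    "space", "congruency", "rt", "response_ok",
]
BST_COLUMNS = [
    "participant_id", "group", "timepoint", "block_index", "background",
    "background_side", "circle_colour", "congruency", "rt", "accurate",
    "timed_out",
]


def write_trials(trials_df: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV; missing RTs become empty fields."""
    trials_df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path, task: str = "llcct") -> pd.DataFrame:
    """Read a trial table, validating the schema for the given task
    ("llcct" or "bst"); empty rt fields parse as missing, never zero."""
    df = pd.read_csv(path, encoding="utf-8")
    required = LLCCT_COLUMNS if task == "llcct" else BST_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    bad = df[df["rt"].notna() & (df["rt"] <= 0)]
    if len(bad):
        raise DataError(
            f"{path}: non-positive rt in rows {bad.index.tolist()[:10]}"
        )
    return df


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------


def effect_table(
    post: PosteriorDraws,
    names: Sequence[str] | None = None,
    to_ms: bool = True,
    decimals: int = 3,
) -> pd.DataFrame:
    """The study's table layout for a fitted model's effects.

    Columns: Mode, HDI low/high (milliseconds for RT models when
    ``to_ms``), n_eff, R-hat, BF10 (capped display) and the hypothesis
    label.  Every row carries its own convergence diagnostics; rows
    violating a gate are flagged rather than dropped.
    """
    names = list(names) if names is not None else post.meta["terms"]
    scale = 1000.0 if (to_ms and post.scale == "seconds") else 1.0
    rows = []
    for n in names:
        s = summarize_effect(post.chains(n), name=n)
        rows.append(
            {
                "effect": n,
                "mode": round(s.mode * scale, decimals),
                "hdi_low": round(s.hdi_low * scale, decimals),
                "hdi_high": round(s.hdi_high * scale, decimals),
                "n_eff": round(s.n_eff),
                "rhat": round(s.rhat, 3),
                "bf10": format_bf(s.bf10),
                "bf10_raw": s.bf10,
                "hypothesis": s.hypothesis,
                "formatted": s.formatted(decimals=2, scale=scale),
                "converged": (s.rhat < 1.1) and (s.n_eff > 10),
            }
        )
    return pd.DataFrame(rows)


def ce_cell_decisions(
    post: PosteriorDraws, factor: str = "space", to_ms: bool = True
) -> pd.DataFrame:
    """Marginal-posterior decisions for the congruency-effect cells.

    For the visuo-tactile task: the homolateral-minus-bilateral
    difference per (group, timepoint) — the peripersonal-space
    signature.  For the body-sidedness task: each background's effect
    against zero per (group, timepoint).
    """
    scale = 1000.0 if to_ms else 1.0
    rows = []
    levels = ("homolateral", "bilateral") if factor == "space" else ("hand", "foot")
    for g in designs.GROUPS:
        for tp in designs.TIMEPOINTS:
            if factor == "space":
                contrast = coding.cell_contrast(levels[0], g, tp) - \
                    coding.cell_contrast(levels[1], g, tp)
                cells = [(f"{g}/{tp} homolateral-bilateral", contrast)]
            else:
                cells = [
                    (f"{g}/{tp} {lv}",
                     coding.cell_contrast(lv, g, tp, factor="background"))
                    for lv in levels
                ]
            for label, contrast in cells:
                mc = marginal_cell(post, contrast, label=label)
                lo, hi = posterior.hdi(mc.draws)
                rows.append(
                    {
                        "cell": label,
                        "mode": round(posterior.posterior_mode(mc.draws) * scale, 3),
                        "hdi_low": round(lo * scale, 3),
                        "hdi_high": round(hi * scale, 3),
                        "pr_positive": round(mc.pr_positive, 2),
                        "decision": mc.decision,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one data source: either ``data_dir`` (CSV tables produced
    by an earlier run or an external dataset) or synthetic generation
    from a seed.  ``iterations``/``warmup``/``chains`` apply to all
    model fits; RT-model effects display in milliseconds.
    """

    data_dir: str | None = None
    synthetic: bool = True
    seed: int = 0
    n_participants: int = 15
    n_motor: int = 8
    repeats_per_cell: int = 8
    bst_repeats: int = 6
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    clinical_iterations: int = 2000
    ppp_replicates: int = 200
    use_table1_cohort: bool = True
    analyses: tuple[str, ...] = (
        "clinical", "llcct_real", "llcct_void", "bst", "covariates"
    )

    def __post_init__(self) -> None:
        if self.synthetic == (self.data_dir is not None):
            raise ValueError(
                "exactly one of synthetic=True or data_dir must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _two_level_code(values, pos_level, neg_level, pos=0.5, neg=-0.5):
    v = pd.Series(values)
    return v.map({pos_level: pos, neg_level: neg}).to_numpy(float)


def _clinical_models(profiles, clin_df, spec_kw) -> dict[str, pd.DataFrame]:
    """Ordinal models (Group x Time) for PSFS/MAS/MRC, Group-only
    ordinal models for NLI and VMIQ-2 (with Perspective), and robust
    linear models for Age and Lesion Onset."""
    out = {}
    g_map = {p.id: p.group for p in profiles}

    # longitudinal ordinal scales: Group, Time(linear, quadratic), Group:Time
    for scale in ("psfs_frequency", "psfs_intensity", "mas", "mrc"):
        df = clin_df
        g = _two_level_code(df["group"], "Motor+MI", "Motor")
        tl = df["timepoint"].map(coding.TIME_LINEAR).to_numpy()
        tq = df["timepoint"].map(coding.TIME_QUADRATIC).to_numpy()
        X = np.column_stack([g, tl, tq, g * tl, g * tq])
        terms = ["Group", "Time", "Time^2", "Group:Time", "Group:Time^2"]
        try:
            post = fit_ordinal_model(
                df[scale].to_numpy(), X,
                OrdinalModelSpec(**spec_kw), term_names=terms,
            )
            out[scale] = effect_table(post, terms, to_ms=False)
        except models.DegenerateDataError:
            out[scale] = pd.DataFrame()

    # T0 cross-sectional: NLI ordinal, VMIQ-2 ordinal with Perspective
    g0 = np.array([0.5 if p.group == "Motor+MI" else -0.5 for p in profiles])
    nli = np.array([coding.nli_rank(p.nli_label) for p in profiles])
    post = fit_ordinal_model(nli, g0[:, None], OrdinalModelSpec(**spec_kw),
                             term_names=["Group"])
    out["nli"] = effect_table(post, ["Group"], to_ms=False)

    vm_rows = []
    for p in profiles:
        for persp, score in (("1PP", p.vmiq2_1pp), ("3PP", p.vmiq2_3pp),
                             ("KIN", p.vmiq2_kin)):
            vm_rows.append({"group": p.group, "persp": persp, "score": score})
    vm = pd.DataFrame(vm_rows)
    g = _two_level_code(vm["group"], "Motor+MI", "Motor")
    # Helmert-style sum-to-zero codes for the three perspectives
    p1 = vm["persp"].map({"1PP": 1.0, "3PP": -1.0, "KIN": 0.0}).to_numpy()
    p2 = vm["persp"].map({"1PP": 1.0, "3PP": 1.0, "KIN": -2.0}).to_numpy()
    X = np.column_stack([g, p1, p2, g * p1, g * p2])
    terms = ["Group", "Perspective1", "Perspective2",
             "Group:Perspective1", "Group:Perspective2"]
    post = fit_ordinal_model(vm["score"].to_numpy(), X,
                             OrdinalModelSpec(**spec_kw), term_names=terms)
    out["vmiq2"] = effect_table(post, terms, to_ms=False)

    # continuous: Age, Lesion Onset (robust Student-t)
    for name, vals in (
        ("age", [p.age_years for p in profiles]),
        ("lesion_onset", [p.lesion_onset_years for p in profiles]),
    ):
        X = np.column_stack([np.ones(len(profiles)), g0])
        post = fit_robust_linear(np.asarray(vals, float), X,
                                 RobustLinearSpec(**spec_kw),
                                 term_names=["Intercept", "Group"])
        out[name] = effect_table(post, ["Intercept", "Group"], to_ms=False)
    return out


@dataclass
class ReportBundle:
    config: RunConfig
    cohort: CohortSummary
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    decisions: dict[str, pd.DataFrame] = field(default_factory=dict)
    diagnostics: dict[str, dict] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, truth: TrueEffectMap | None = None
                 ) -> ReportBundle:
    """Execute the full analysis sequence and return all report tables.

    With ``synthetic=True`` the study is simulated from ``truth``
    (defaults to the package's study-condition ground truth); with
    ``data_dir`` the trial tables are read from CSV.
    """
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("cohort", "clinical", "llcct", "bst", "fit_real", "fit_void",
              "fit_bst", "fit_cov", "ppp")}
    log = [f"run seed: {config.seed}", f"stage seeds: {seeds}"]

    stage = "load"
    try:
        if config.synthetic:
            truth = truth or designs.default_truth()
            if config.use_table1_cohort and config.n_participants == 15:
                profiles = designs.with_clinical_scores(
                    designs.table1_cohort(), seed=seeds["cohort"]
                )
            else:
                profiles = designs.generate_cohort(
                    config.n_participants, config.n_motor, seed=seeds["cohort"]
                )
            llcct = designs.llcct_frame(
                designs.simulate_llcct_study(
                    profiles, truth, seeds["llcct"],
                    repeats_per_cell=config.repeats_per_cell,
                )
            )
            bst = designs.bst_frame(
                designs.simulate_bst_study(
                    profiles, truth, seeds["bst"], repeats=config.bst_repeats
                )
            )
            clin = designs.clinical_longitudinal(profiles, seed=seeds["clinical"])
        else:
            root = Path(config.data_dir)
            llcct = read_trials(root / "llcct.csv", "llcct")
            bst = read_trials(root / "bst.csv", "bst")
            cohort_df = pd.read_csv(root / "cohort.csv")
            profiles = _profiles_from_frame(cohort_df)
            clin = pd.read_csv(root / "clinical.csv")
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise StageError(stage, exc) from exc

    bundle = ReportBundle(config=config, cohort=descriptive_stats(profiles),
                          log=log)
    bundle.tables["data_llcct"] = llcct
    bundle.tables["data_bst"] = bst

    fit_kw = dict(chains=config.chains, iterations=config.iterations,
                  warmup=config.warmup)
    clin_kw = dict(chains=config.chains,
                   iterations=config.clinical_iterations,
                   warmup=config.clinical_iterations // 2)

    if "clinical" in config.analyses:
        stage = "clinical"
        try:
            clin_tables = _clinical_models(
                profiles, clin, {**clin_kw, "seed": seeds["clinical"]}
            )
            for k, v in clin_tables.items():
                bundle.tables[f"clinical_{k}"] = v
            log.append("clinical models fitted")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    for cond, key in (("REAL", "llcct_real"), ("VOID", "llcct_void")):
        if key not in config.analyses:
            continue
        stage = key
        try:
            sub = llcct[llcct["condition"] == cond]
            post = fit_congruency_model(
                sub, CongruencyModelSpec(seed=seeds[f"fit_{cond.lower()}"],
                                         **fit_kw)
            )
            ppp = congruency_ppp(post, n_rep=config.ppp_replicates,
                                 seed=seeds["ppp"])
            bundle.tables[key] = effect_table(post)
            bundle.decisions[key] = ce_cell_decisions(post, factor="space")
            report = diagnose(post, post.meta["terms"], ppp=ppp)
            bundle.diagnostics[key] = {
                "ppp": ppp, "rhat": report.rhat, "n_eff": report.n_eff,
                "all_ok": report.all_ok,
            }
            if key == "llcct_real":
                bundle.tables["_post_real"] = post  # reused by covariates
            log.append(f"{key} fitted (ppp={ppp:.2f})")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "bst" in config.analyses:
        stage = "bst"
        try:
            post = fit_congruency_model(
                bst, CongruencyModelSpec(factor="background",
                                         seed=seeds["fit_bst"], **fit_kw)
            )
            ppp = congruency_ppp(post, n_rep=config.ppp_replicates,
                                 seed=seeds["ppp"])
            bundle.tables["bst"] = effect_table(post)
            bundle.decisions["bst"] = ce_cell_decisions(post, factor="background")
            report = diagnose(post, post.meta["terms"], ppp=ppp)
            bundle.diagnostics["bst"] = {
                "ppp": ppp, "rhat": report.rhat, "n_eff": report.n_eff,
                "all_ok": report.all_ok,
            }
            log.append(f"bst fitted (ppp={ppp:.2f})")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "covariates" in config.analyses:
        stage = "covariates"
        try:
            spec = CovariateModelSpec(seed=seeds["fit_cov"], **clin_kw)
            resp = participant_ce_summary(llcct, timepoint="T1",
                                          condition="REAL",
                                          cell=("space", "homolateral"))
            ordered = [resp[p.id] for p in profiles]
            post = fit_covariate_model(ordered, profiles, spec)
            bundle.tables["covariates_llcct"] = effect_table(post,
                                                             models.COVARIATE_TERMS)
            resp_b = participant_ce_summary(bst, timepoint="T1",
                                            condition=None,
                                            cell=("background", "foot"))
            ordered_b = [resp_b[p.id] for p in profiles]
            post_b = fit_covariate_model(ordered_b, profiles, spec)
            bundle.tables["covariates_bst"] = effect_table(post_b,
                                                           models.COVARIATE_TERMS)
            log.append("covariate models fitted")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    return bundle


def _profiles_from_frame(df: pd.DataFrame) -> list[ParticipantProfile]:
    profs = []
    for r in df.itertuples():
        profs.append(
            ParticipantProfile(
                id=r.id, age_years=r.age_years,
                lesion_onset_years=r.lesion_onset_years,
                n_sessions=int(r.n_sessions), nli_label=r.nli_label,
                ais=r.ais, group=r.group, motor_modality=r.motor_modality,
                gender=r.gender,
                psfs_frequency=int(r.psfs_frequency),
                psfs_intensity=int(r.psfs_intensity),
                mas=int(r.mas),
                mrc_movements=tuple(
                    int(v) for v in str(r.mrc_movements).split(";")
                ),
                vmiq2_1pp=int(r.vmiq2_1pp), vmiq2_3pp=int(r.vmiq2_3pp),
                vmiq2_kin=int(r.vmiq2_kin),
            )
        )
    return profs


def write_report(bundle: ReportBundle, out_dir) -> None:
    """Serialise a report bundle: one CSV per table plus a JSON summary
    of diagnostics, cohort descriptives and the run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables.items():
        # raw simulated/loaded data tables live in the bundle for reuse
        # but are not part of the report
        if name.startswith(("_", "data_")) or not isinstance(table, pd.DataFrame):
            continue
        table.to_csv(out / f"{name}.csv", index=False, encoding="utf-8")
    for name, table in bundle.decisions.items():
        table.to_csv(out / f"decisions_{name}.csv", index=False,
                     encoding="utf-8")
    summary = {
        "config": {k: v for k, v in asdict(bundle.config).items()},
        "cohort": asdict(bundle.cohort),
        "diagnostics": bundle.diagnostics,
        "log": bundle.log,
    }
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
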