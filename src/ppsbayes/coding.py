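"""Factor coding and design-matrix construction for the congruency models.

Two-level factors use sum-to-zero +/-0.5 codes (Space: homolateral +0.5;
Background: hand +0.5; Group: Motor+MI +0.5).  The three timepoints enter
as orthogonal linear (-1, 0, 1) and quadratic (1, -2, 1) polynomial
contrasts.  The population-level design has exactly the 12 terms of the
fitted effect tables: intercept, three main effects, the quadratic time
term, and all two- and three-way interactions, with interaction columns
as elementwise products of their parents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPACE_CODE = {"homolateral": 0.5, "bilateral": -0.5}
BACKGROUND_CODE = {"hand": 0.5, "foot": -0.5}
GROUP_CODE = {"Motor+MI": 0.5, "Motor": -0.5}
TIME_LINEAR = {"T0": -1.0, "T1": 0.0, "T2": 1.0}
TIME_QUADRATIC = {"T0": 1.0, "T1": -2.0, "T2": 1.0}


class DesignError(ValueError):
    pass


def population_terms(factor_name: str = "Space") -> list[str]:
    """The 12 population-level term names, in fitted-table order."""
    f = factor_name
    return [
        "Intercept",
        f,
        "Group",
        "Time",
        "Time^2",
        f"{f}:Group",
        f"{f}:Time",
        f"{f}:Time^2",
        "Group:Time",
        "Group:Time^2",
        f"{f}:Group:Time",
        f"{f}:Group:Time^2",
    ]


def _design_from_codes(s: np.ndarray, g: np.ndarray, tl: np.ndarray,
                       tq: np.ndarray) -> np.ndarray:
    one = np.ones_like(s)
    return np.column_stack(
        [one, s, g, tl, tq, s * g, s * tl, s * tq, g * tl, g * tq,
         s * g * tl, s * g * tq]
    )


def build_ce_design(trials: pd.DataFrame, factor: str = "space"):
    """Population-level (X), group-level (Z) design matrices and the
    congruency indicator for answered test trials of a single condition.

    ``factor`` is ``"space"`` for the visuo-tactile task or
    ``"background"`` for the body-sidedness task.  X has the 12 columns
    of ``population_terms``; Z has (intercept, time-linear,
    time-quadratic, factor) columns — the per-participant varying
    effects.  The congruency indicator c is 1 on incongruent trials and
    0 on congruent trials, so the latent Congruency Effect is exactly
    the incongruent-minus-congruent RT shift.

    Returns ``(X, Z, c, participant_index, participant_ids, rt)``.
    """
    if factor == "space":
        if "condition" in trials and trials["condition"].nunique() > 1:
            raise DesignError(
                "trials mix REAL and VOID conditions; analyse them separately"
            )
        code_map, col = SPACE_CODE, "space"
    elif factor == "background":
        code_map, col = BACKGROUND_CODE, "background"
    else:
        raise DesignError(f"unknown factor {factor!r}")

    t = trials
    if "trial_kind" in t:
        t = t[t["trial_kind"] == "test"]
    t = t[t["rt"].notna()].reset_index(drop=True)
    if t.empty:
        raise DesignError("no answered test trials with RTs")

    s = t[col].map(code_map).to_numpy(float)
    g = t["group"].map(GROUP_CODE).to_numpy(float)
    tl = t["timepoint"].map(TIME_LINEAR).to_numpy(float)
    tq = t["timepoint"].map(TIME_QUADRATIC).to_numpy(float)
    if np.isnan(s).any() or np.isnan(g).any() or np.isnan(tl).any():
        raise DesignError("unrecognised factor level in trials")

    X = _design_from_codes(s, g, tl, tq)
    Z = np.column_stack([np.ones_like(s), tl, tq, s])
    c = (t["congruency"] == "incongruent").to_numpy(float)
    ids = pd.Categorical(t["participant_id"])
    return X, Z, c, ids.codes.astype(np.int64), list(ids.categories), t["rt"].to_numpy(float)


def cell_contrast(factor_level: str, group: str, timepoint: str,
                  factor: str = "space") -> np.ndarray:
    """Contrast vector over the 12 population terms reconstructing the
    Congruency Effect of one (factor level, group, timepoint) cell."""
    code_map = SPACE_CODE if factor == "space" else BACKGROUND_CODE
    s = np.array([code_map[factor_level]])
    g = np.array([GROUP_CODE[group]])
    tl = np.array([TIME_LINEAR[timepoint]])
    tq = np.array([TIME_QUADRATIC[timepoint]])
    return _design_from_codes(s, g, tl, tq)[0]


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (n-1 divisor)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("zscore needs >= 2 distinct values")
    return (v - v.mean()) / v.std(ddof=1)


_NLI_PREFIX_BASE = {"C": 0, "T": 8, "L": 20}
_NLI_MAX = {"C": 8, "T": 12, "L": 5}


def nli_rank(label: str) -> int:
    """Rostral-to-caudal integer rank of a spinal-segment label:
    C1..C8 -> 1..8, T1..T12 -> 9..20, L1..L5 -> 21..25."""
    label = str(label).strip().upper()
    prefix, num = label[:1], label[1:]
    if prefix not in _NLI_PREFIX_BASE or not num.isdigit():
        raise ValueError(f"unknown spinal segment {label!r}")
    k = int(num)
    if not 1 <= k <= _NLI_MAX[prefix]:
        raise ValueError(f"unknown spinal segment {label!r}")
    return _NLI_PREFIX_BASE[prefix] + k
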