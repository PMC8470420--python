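"""Collect the stage outputs into a single human-readable report.

Prints the cohort descriptives, the effect tables of every fitted model
(milliseconds, mode {HDI} format with BF10 and hypothesis labels) and
the marginal-posterior decisions, and writes the combined plain-text
report to results/report.txt.
"""

from pathlib import Path

import pandas as pd

from ppsbayes import pipeline

RESULTS = Path("results")
OUT = RESULTS / "report.txt"

sections = []

cohort = pd.read_csv(RESULTS / "data" / "cohort.csv")
profiles = pipeline._profiles_from_frame(cohort)
summary = pipeline.descriptive_stats(profiles)
sections.append(
    "COHORT\n"
    f"  n = {summary.n}; groups {summary.counts['group']}\n"
    f"  age mean {summary.means['age_years']} (pop. SD {summary.sds['age_years']})\n"
    f"  lesion onset mean {summary.means['lesion_onset_years']} "
    f"(pop. SD {summary.sds['lesion_onset_years']})\n"
    f"  sessions mean {summary.means['n_sessions']}; "
    f"NLI levels {summary.counts['nli_label']}; AIS {summary.counts['ais']}"
)

tables = [
    ("LLCCT REAL effects", RESULTS / "llcct" / "effects_real.csv"),
    ("LLCCT REAL cell decisions", RESULTS / "llcct" / "cells_real.csv"),
    ("LLCCT VOID effects", RESULTS / "llcct" / "effects_void.csv"),
    ("BST effects", RESULTS / "bst" / "effects.csv"),
    ("BST cell decisions", RESULTS / "bst" / "cells.csv"),
    ("Covariates (LLCCT T1)", RESULTS / "covariates" / "effects_llcct.csv"),
    ("Covariates (BST T1)", RESULTS / "covariates" / "effects_bst.csv"),
]
for title, path in tables:
    if not path.exists():
        sections.append(f"{title}\n  (not computed - run the earlier stages)")
        continue
    df = pd.read_csv(path)
    drop = [c for c in ("bf10_raw", "formatted") if c in df.columns]
    sections.append(f"{title}\n{df.drop(columns=drop).to_string(index=False)}")

report = "\n\n".join(sections) + "\n"
OUT.write_text(report, encoding="utf-8")
print(report)
print(f"written to {OUT}")
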