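"""Simulate the synthetic rehabilitation study and write its data tables.

Generates the 15-participant cohort (the published demographics with
synthetic clinical-scale scores), the longitudinal clinical scores, and
the full visuo-tactile (LLCCT, REAL + VOID) and body-sidedness (BST)
trial tables with ex-Gaussian reaction times carrying the study-condition
ground truth: a 30 ms peripersonal-space signature (homolateral 40 ms vs
bilateral 10 ms) only in the Motor+MI group at T1.

Writes results/data/{cohort,clinical,llcct,bst}.csv.
"""

import sys
from pathlib import Path

import numpy as np

from ppsbayes import designs, pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(SEED)
truth = designs.default_truth()
profiles = designs.with_clinical_scores(
    designs.table1_cohort(), seed=int(rng.integers(2**31))
)

designs.cohort_frame(profiles).to_csv(OUT / "cohort.csv", index=False)
designs.clinical_longitudinal(profiles, seed=int(rng.integers(2**31))).to_csv(
    OUT / "clinical.csv", index=False
)

llcct = designs.llcct_frame(
    designs.simulate_llcct_study(profiles, truth, int(rng.integers(2**31)))
)
pipeline.write_trials(llcct, OUT / "llcct.csv")
bst = designs.bst_frame(
    designs.simulate_bst_study(profiles, truth, int(rng.integers(2**31)))
)
pipeline.write_trials(bst, OUT / "bst.csv")

summary = pipeline.descriptive_stats(profiles)
print(f"cohort: n={summary.n}, groups={summary.counts['group']}")
print(f"lesion onset mean={summary.means['lesion_onset_years']} "
      f"SD={summary.sds['lesion_onset_years']}")
print(f"LLCCT trials: {len(llcct)} "
      f"({llcct['rt'].notna().sum()} answered test trials)")
print(f"BST trials: {len(bst)} ({bst['rt'].notna().sum()} answered)")
print(f"tables written to {OUT}/")
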