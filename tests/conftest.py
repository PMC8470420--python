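import numpy as np
import pandas as pd
import pytest

from ppsbayes import designs
from ppsbayes.designs import with_clinical_scores, table1_cohort, llcct_frame
from ppsbayes.models import CongruencyModelSpec, fit_congruency_model


@pytest.fixture(scope="session")
def table1():
    return table1_cohort()


@pytest.fixture(scope="session")
def scored_profiles():
    return with_clinical_scores(table1_cohort(), seed=11)


@pytest.fixture(scope="session")
def small_llcct_data(scored_profiles):
    """Reduced-scale simulated visuo-tactile dataset (REAL condition,
    2 factorial repeats) used by the model unit tests."""
    truth = designs.default_truth()
    trials = designs.simulate_llcct_study(
        scored_profiles, truth, seed=5, conditions=("REAL",),
        repeats_per_cell=2,
    )
    return llcct_frame(trials), truth


@pytest.fixture(scope="session")
def small_llcct_fit(small_llcct_data):
    """One reduced-iteration fit of the congruency model, shared across
    tests that only inspect its structure."""
    df, truth = small_llcct_data
    post = fit_congruency_model(
        df, CongruencyModelSpec(seed=9, iterations=800, warmup=400)
    )
    return post, truth
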