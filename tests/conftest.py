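import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across read-only tests."""
    from sidefx.cohort import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_subjects=250, n_genes=12, seed=42))


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    from sidefx.phenotypes import score_profiles

    return score_profiles(small_cohort.medis, day=10)
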