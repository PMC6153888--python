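import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import distaniso as da

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def test_profile_params():
    return da.solve_test_profile(1.55, 5.0, 2.5)


@pytest.fixture(scope="session")
def test_profile(test_profile_params):
    return da.build_test_profile(test_profile_params)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study's design scale (24 participants, 4 of whom
    use the duration strategy)."""
    return da.simulate_cohort(da.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A screened 20-participant cohort without duration-strategy members."""
    cfg = da.CohortConfig(n_participants=20, duration_strategy_fraction=0.0, seed=11)
    table = da.simulate_cohort(cfg)
    kept, _ = da.screen_participants(table)
    return kept


@pytest.fixture(scope="session")
def upright_trials(clean_cohort):
    return clean_cohort[clean_cohort["orientation"] == "upright"]
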