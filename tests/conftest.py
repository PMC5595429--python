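import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (12 patients, 25 controls), seed 7."""
    from recmem.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    from recmem.pipeline import score_subjects

    trials, groups = default_cohort
    return score_subjects(trials), groups


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
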