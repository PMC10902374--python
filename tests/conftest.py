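import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient labelled cohort with 10% MCAR missingness."""
    from ctdnatools.simulate import CohortSimConfig, simulate_clinical_cohort

    return simulate_clinical_cohort(
        CohortSimConfig(n_patients=300, missing_rate=0.10, seed=11)
    )


@pytest.fixture(scope="session")
def complete_cohort():
    """200-patient labelled cohort with no missingness."""
    from ctdnatools.simulate import CohortSimConfig, simulate_clinical_cohort

    return simulate_clinical_cohort(CohortSimConfig(n_patients=200, seed=7))


FAST_HYPER = {"num_round": 10, "max_depth": 2, "eta": 0.1, "subsample": 0.75}


@pytest.fixture(scope="session")
def fast_hyper():
    return dict(FAST_HYPER)
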