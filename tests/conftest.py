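import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smsfreq as sf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> sf.Cohort:
    """The generator's default study conditions at a fixed seed."""
    return sf.generate_cohort(sf.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def clean_cohort(default_cohort) -> sf.Cohort:
    cohort, _ = sf.clean_cohort(default_cohort)
    return cohort


@pytest.fixture(scope="session")
def noise_free_cohort() -> sf.Cohort:
    """Default archetype mixture without missingness or constants."""
    return sf.generate_cohort(
        sf.CohortSpec(n_subjects=129, missing_rate=0.0, constant_rate=0.0, seed=1)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
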