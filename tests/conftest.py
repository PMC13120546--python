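import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_cohort():
    """Table-calibrated ten-subject cohort with sensor noise switched off."""
    from gaitwalker import synth

    return synth.default_cohort(seed=0, noise_sd_force=0.0)


@pytest.fixture(scope="session")
def noisy_cohort():
    from gaitwalker import synth

    return synth.default_cohort(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
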