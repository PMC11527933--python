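import numpy as np
import pytest

from mrpet.schedule import default_schedule
from mrpet.simulate import default_subject_params, simulate_subject


@pytest.fixture(scope="session")
def extended_schedule():
    return default_schedule(extended=True)


@pytest.fixture(scope="session")
def literal_schedule():
    return default_schedule(extended=False)


@pytest.fixture(scope="session")
def noiseless_subject():
    """Default subject with all noise sources disabled: every configured
    value is realised exactly."""
    return simulate_subject(default_subject_params(noise_scale=0.0))


@pytest.fixture(scope="session")
def noisy_subject():
    return simulate_subject(default_subject_params(seed=7, noise_scale=0.02))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
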