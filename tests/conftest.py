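import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_eeg():
    """A 10-second interictal-profile trace shared by codec tests."""
    from eegcodec import generate_eeg

    return generate_eeg("ds3_interictal_opposite", 10.0, seed=3)
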