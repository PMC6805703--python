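import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from triquant import synthgen

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def clean_symmetric_brain():
    """Noiseless healthy phantom: two equal ellipses per slice."""
    return synthgen.generate_brain(synthgen.PhantomParams(noise_sd=0.0, seed=11))


@pytest.fixture
def injured_brain():
    """Noisy phantom with swelling, infarct and an Evans-blue core."""
    params = synthgen.PhantomParams(
        infarct_fraction=0.10,
        swelling_factor=1.10,
        eb_fraction=0.6,
        seed=23,
    )
    return synthgen.generate_brain(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
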