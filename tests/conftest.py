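import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import despeckle as dsp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom():
    return dsp.generate_shepp_logan(200)


@pytest.fixture(scope="session")
def noisy(phantom):
    """Phantom with speckle at the reference study level (variance 0.1)."""
    return dsp.add_speckle(phantom, dsp.SpeckleParams(variance=0.1, seed=7))


@pytest.fixture(scope="session")
def phantom128():
    return dsp.generate_shepp_logan(128)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
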