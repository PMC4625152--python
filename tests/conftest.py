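import numpy as np
import pytest

from sfhi import AcquisitionSettings, GridSpec, simulate_reference


@pytest.fixture
def grid8():
    """Default mesh: pitch 8 px, 5% duty, 86% mean transmission."""
    return GridSpec()


@pytest.fixture
def noise_free():
    return AcquisitionSettings(fluence=1.0e4, rng_seed=0, noise_enabled=False)


@pytest.fixture
def reference256(grid8, noise_free):
    return simulate_reference(grid8, (256, 256), settings=noise_free)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
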