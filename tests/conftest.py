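import numpy as np
import pytest
from hypothesis import settings

from tirekit.optics import default_stack
from tirekit.synthetic import GeneratorConfig, NoiseSpec

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stack():
    return default_stack()


@pytest.fixture()
def quiet_config():
    """Generator with all noise switched off (deterministic physics only)."""
    return GeneratorConfig(noise=NoiseSpec(sigma_psi=0.0, sigma_delta=0.0, sigma_trace=0.0, seed=0))


@pytest.fixture()
def coarse_grid():
    """A sparser wavelength grid (5 nm) that keeps optimization-heavy tests fast."""
    return np.arange(450.0, 1000.0 + 1e-9, 5.0)
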