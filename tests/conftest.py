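import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from fmmecg import fit_beat, pattern_presets, simulate_beat


@pytest.fixture(scope="session")
def presets():
    return pattern_presets()


@pytest.fixture(scope="session")
def normal_preset(presets):
    return presets["NORMAL"]


@pytest.fixture(scope="session")
def normal_beat_clean(normal_preset):
    """Noiseless typical beat on the default 500-sample phase grid."""
    return simulate_beat(normal_preset.params, 0.0, n=500, seed=1)


@pytest.fixture(scope="session")
def normal_fit_clean(normal_beat_clean):
    """One fitted noiseless typical beat, shared across tests (fits are the
    expensive step)."""
    return fit_beat(normal_beat_clean)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
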