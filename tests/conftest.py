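import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psiirepair import NoiseModel, generate_dataset, make_preset

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

PRESET_NAMES = ("MIT9313_30", "MIT9313_90", "MED4_30", "MED4_260",
                "WH8102_30", "WH8102_260")


@pytest.fixture(scope="session")
def med4_hl_preset():
    return make_preset("MED4_260")


@pytest.fixture(scope="session")
def zero_noise_dataset(med4_hl_preset):
    """Noise-free 3-replicate MED 4 high-light experiment."""
    return generate_dataset(med4_hl_preset, NoiseModel.zero(11), n=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
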