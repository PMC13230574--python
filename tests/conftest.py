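import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from emowave import RadarConfig

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_config() -> RadarConfig:
    """The full 60-GHz study configuration (12 virtual channels)."""
    return RadarConfig()


@pytest.fixture(scope="session")
def small_config(table2_config) -> RadarConfig:
    """A reduced configuration for cheap unit tests: 2 virtual channels,
    64 fast-time samples at 1.28 MHz (same range resolution as the study
    configuration) and a 20 Hz frame rate."""
    return dataclasses.replace(table2_config, adc_samples=64,
                               adc_sample_rate=1.28e6, n_tx=1, n_rx=2,
                               frame_rate=20.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
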