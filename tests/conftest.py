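import numpy as np
import pytest

from cipkit import ScanConfig, SpeciesSpec, particles_for_focal_number


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small single-channel scan used for fast correlation tests."""
    return ScanConfig(frame_shape=(64, 64), n_frames=60,
                      n_spectral_channels=1)


@pytest.fixture
def small_species(small_config):
    box = 1.5 * max(small_config.scan_field_um)
    n = particles_for_focal_number(2.5, small_config, box)
    return SpeciesSpec("tracer", 1.0, 50.0, np.array([1.0]), n)
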