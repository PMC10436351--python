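import numpy as np
import pytest

from mpsim import OpticalConfig, SphereScatterer


@pytest.fixture
def config():
    """Small, fast optical configuration (landing-assay geometry)."""
    return OpticalConfig(grid_size=64, pixel_size=70e-9,
                         mask_transmission=0.01, mask_phase=0.0,
                         polarization="circular", pupil_samples=192)


@pytest.fixture
def hsp_sphere():
    return SphereScatterer(radius=5.6e-9, n_particle=1.480, n_medium=1.333)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
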