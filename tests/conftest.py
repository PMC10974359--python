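import numpy as np
import pytest

from dhmkit import (
    OpticalConstants,
    SimConfig,
    make_microsphere_phantom,
    synthesize_hologram,
)

SHAPE = (256, 256)
PITCH = 0.1  # μm/px
DIAMETER = 10.0  # μm


@pytest.fixture(scope="session")
def constants() -> OpticalConstants:
    return OpticalConstants()  # 532 nm, Δn = 0.06, 0.1 μm/px


@pytest.fixture(scope="session")
def sphere_phantom():
    """10 μm sphere centered exactly on a grid pixel (peak lands on a sample)."""
    return make_microsphere_phantom(SHAPE, PITCH, DIAMETER, [(12.8, 12.8)])


@pytest.fixture(scope="session")
def clean_pair(sphere_phantom, constants):
    """Noise-free object/reference hologram pair at the default carrier."""
    cfg = SimConfig(carrier=(0.2, 0.0), shape=SHAPE, noise_sigma=0.0)
    return synthesize_hologram(sphere_phantom, constants, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
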