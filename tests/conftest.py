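import numpy as np
import pytest

from ezdetect.synthetic_oct import PhantomConfig, generate_phantom


def small_config(**overrides) -> PhantomConfig:
    """A quick 64x16x96 phantom for unit tests (full geometry, smaller grid)."""
    kwargs = dict(
        nx=64, ny=16, nz=96,
        surface1_depth=16.0,
        undulation_amplitude=(2.0, 1.0),
        fovea_depth=4.0,
        n_disruptions=1,
        disruption_radius=(6.0, 7.0),
        n_vessels=2,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, vessel-free, disruption-free small phantom with truth."""
    cfg = small_config(speckle_scale=0.0, n_vessels=0, n_disruptions=0)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise small phantom with one disruption and vessels."""
    return generate_phantom(small_config(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
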