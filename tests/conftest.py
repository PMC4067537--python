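import numpy as np
import pytest

from kinquant import SimConfig, simulate_field


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimConfig:
    """A small fully deterministic field: no background, no noise."""
    return SimConfig(
        field_shape=(15, 320, 320),
        background_dapi=0.0,
        background_gfp=0.0,
        read_noise_sd=0.0,
        poisson_noise=False,
        n_phage_per_class=2,
        n_kinetochores=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_field(noiseless_cfg):
    return simulate_field(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_cfg() -> SimConfig:
    """Default photon budget and noise model on a reduced field."""
    return SimConfig(field_shape=(21, 512, 512), seed=11)


@pytest.fixture(scope="session")
def noisy_field(noisy_cfg):
    return simulate_field(noisy_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
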