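import numpy as np
import pytest

from diffuserlf import (
    DiffuserSim,
    calibrate,
    generate_point_pattern,
    small_geometry,
)


@pytest.fixture(scope="session")
def tiny_config():
    """8x8 spatial, 2x2 angular, 64x64 sensor: dense-matrix scale."""
    return small_geometry(n_s=8, n_t=8, n_u=2, n_v=2, sensor=64)


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return DiffuserSim(config=tiny_config, seed=7, support_px=(16, 16))


@pytest.fixture(scope="session")
def tiny_pattern(tiny_sim):
    return generate_point_pattern(tiny_sim)


@pytest.fixture(scope="session")
def tiny_kernel(tiny_pattern, tiny_config):
    return calibrate(tiny_pattern, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
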