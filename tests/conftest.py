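import numpy as np
import pytest

from topwet import GeneratorConfig, generate_basins, generate_sm_cube


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small but fully-featured study: 12 basins, 3 models, 4 scenarios."""
    return GeneratorConfig(
        n_basins=12,
        pixels_per_basin=300,
        n_models=3,
        year_range=(1984, 2040),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_basins(small_config):
    return generate_basins(small_config)


@pytest.fixture(scope="session")
def small_cube(small_config, small_basins):
    basins, _ = small_basins
    return generate_sm_cube(basins, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
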