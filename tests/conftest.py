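import numpy as np
import pytest

from critnat.grids import GridSpec
from critnat.synthkit import GeneratorConfig, make_landscape
from critnat.workbench import RunConfig


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_rows=24, n_cols=24)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return make_landscape(small_config, seed=11)


@pytest.fixture(scope="session")
def small_run_config(small_config) -> RunConfig:
    return RunConfig(generator=small_config, seed=11, n_species=8, n_languages=4)


@pytest.fixture(scope="session")
def small_context(small_run_config):
    from critnat.workbench import compute_context
    return compute_context(small_run_config)


@pytest.fixture
def line3() -> GridSpec:
    return GridSpec(1, 3)


def random_dem(rng: np.random.Generator, n_rows: int, n_cols: int):
    """Random rough DEM + marine strip on the west edge."""
    elev = rng.uniform(0.0, 50.0, (n_rows, n_cols))
    marine = np.zeros((n_rows, n_cols), dtype=bool)
    marine[:, 0] = rng.random(n_rows) < 0.7
    elev[marine] = -5.0
    return elev, marine
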