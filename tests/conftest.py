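import numpy as np
import pytest

from benthosdm import (
    SeascapeConfig,
    filter_correlated,
    generate_seascape,
    sample_sites,
)


@pytest.fixture(scope="session")
def small_config():
    # small grid keeps unit tests fast; survey sizes scaled down with it
    return SeascapeConfig(grid_rows=32, grid_cols=32, n_train=120, n_test=100, seed=11)


@pytest.fixture(scope="session")
def small_seascape(small_config):
    return generate_seascape(small_config)


@pytest.fixture(scope="session")
def small_sites(small_seascape, small_config):
    return sample_sites(small_seascape, small_config)


@pytest.fixture(scope="session")
def study_seascape():
    """Full study-condition seascape: 64x64, 292/273 sites, 4.5% prevalence."""
    cfg = SeascapeConfig(grid_rows=64, grid_cols=64, seed=1)
    sea = generate_seascape(cfg)
    train, test = sample_sites(sea, cfg)
    retained = filter_correlated(train).retained
    return sea, train, test, retained


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
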