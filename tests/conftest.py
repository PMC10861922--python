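import numpy as np
import pandas as pd
import pytest

from shearshift import synthetic as syn


@pytest.fixture(scope="session")
def coastline():
    return syn.make_toy_coastline()


@pytest.fixture(scope="session")
def grid_1deg(coastline):
    return coastline.rasterize(1.0)


@pytest.fixture(scope="session")
def grid_quarter(coastline):
    return coastline.rasterize(0.25)


@pytest.fixture(scope="session")
def small_summaries():
    """Summary-level population with the default (study-condition) parameters."""
    cfg = syn.PopulationConfig(n_individuals=150, seed=7)
    return cfg, syn.simulate_summaries(cfg, seed=7)


@pytest.fixture(scope="session")
def noisefree_config():
    return syn.PopulationConfig(
        n_individuals=20, seed=3, fix_noise_lat_sd=0.0, fix_noise_lon_sd=0.0,
        fix_dropout_p=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
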