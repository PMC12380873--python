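import numpy as np
import pandas as pd
import pytest

from agroniche import simulate
from agroniche.grids import Grid, Raster, Stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trait_table():
    cfg = simulate.TraitSimConfig(
        n_germplasm=20, n_traits=23, n_reps=5,
        germplasm_sd=10.0, replicate_sd=1.0,
        fertility_fail_fraction=0.25, seed=42,
    )
    table, latent = simulate.generate_trait_table(cfg)
    return table, latent


@pytest.fixture
def small_grid():
    return Grid(ncols=10, nrows=8, xllcorner=100.0, yllcorner=30.0, cellsize=0.5)


@pytest.fixture
def small_landscape():
    cfg = simulate.LandscapeSimConfig(
        extent=(90.0, 95.0, 30.0, 35.0), resolution=0.25, n_layers=4,
        smoothness=3.0, true_coefficients={"env01": 3.0, "env02": -2.0}, seed=7,
    )
    return simulate.generate_landscape(cfg)


def make_raster(values, xll=0.0, yll=0.0, cellsize=1.0):
    values = np.asarray(values, dtype=float)
    grid = Grid(ncols=values.shape[1], nrows=values.shape[0],
                xllcorner=xll, yllcorner=yll, cellsize=cellsize)
    return Raster(values, grid)
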