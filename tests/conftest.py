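import numpy as np
import pytest

import cropdispersal as cd


@pytest.fixture(scope="session")
def all_land_grid():
    """5x5 all-land grid at the equator, 0.5 degree cells."""
    return cd.RasterGrid(np.ones((5, 5)), xllcorner=0.0, yllcorner=-1.25, cellsize=0.5)


@pytest.fixture(scope="session")
def coastal_grid():
    """6x6 grid: west half land, east half water."""
    values = np.zeros((6, 6))
    values[:, :3] = 1.0
    return cd.RasterGrid(values, xllcorner=-10.0, yllcorner=0.0, cellsize=0.5)


@pytest.fixture(scope="session")
def small_scenario():
    """A modest synthetic scenario reused by several test modules."""
    spec = cd.SyntheticScenario(
        n_rows=20, n_cols=20, n_sites=60, n_accessions=40, n_loci=30, seed=3
    )
    return cd.generate_scenario(spec)


@pytest.fixture(scope="session")
def small_landscape(small_scenario):
    return small_scenario.landscape


def random_connected_landscape(n_rows, n_cols, seed, land_fraction=0.7):
    """Helper: random landmass and its landscape model plus mainland cells."""
    spec = cd.SyntheticScenario(
        n_rows=n_rows, n_cols=n_cols, land_fraction=land_fraction, seed=seed
    )
    grid = cd.make_landmass(spec, seed)
    landscape = cd.assemble_landscape(grid, cd.LandscapeParams(0.5, 800.0))
    from cropdispersal.synth import mainland_cells

    return grid, landscape, mainland_cells(grid)
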