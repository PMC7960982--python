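import numpy as np
import pytest

from aquathreat.synthetic_world import GridDefinition


def uniform_grid(n_rows, n_cols, *, area=1.0, n_basins=1, basin_map=None,
                 ecoregion_map=None):
    """Grid with constant cell area and simple basin/ecoregion labels."""
    shape = (n_rows, n_cols)
    if basin_map is None:
        # vertical strips of near-equal width
        cols = np.arange(n_cols)
        edges = np.linspace(0, n_cols, n_basins + 1)
        strip = np.clip(np.searchsorted(edges, cols, side="right") - 1, 0, n_basins - 1)
        basin_map = np.tile(strip, (n_rows, 1))
    if ecoregion_map is None:
        ecoregion_map = np.zeros(shape, dtype=int)
    return GridDefinition(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_area=np.full(shape, float(area)),
        basin_id=np.asarray(basin_map, dtype=int),
        ecoregion_id=np.asarray(ecoregion_map, dtype=int),
        valid_mask=np.ones(shape, dtype=bool),
    )


@pytest.fixture
def grid4():
    """1x4 single-basin grid with unit areas."""
    return uniform_grid(1, 4)


@pytest.fixture
def grid10x10():
    """10x10 grid, four basin strips, two ecoregion bands."""
    eco = np.zeros((10, 10), dtype=int)
    eco[5:, :] = 1
    return uniform_grid(10, 10, n_basins=4, ecoregion_map=eco)


def constant_series(n_years, n_weeks, value):
    return np.full((n_years, n_weeks), float(value))
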