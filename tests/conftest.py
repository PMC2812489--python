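import numpy as np
import pytest

import mosaicpop as mp


@pytest.fixture(scope="session")
def small_layout():
    return mp.BarrierLayout(road_spacing=30, road_width=1, river=True, river_width=1,
                            n_buildings=3, building_size=2, n_lakes=1, lake_radius=3)


@pytest.fixture(scope="session")
def small_landscape(small_layout):
    """60x60, 40 patches, no field margins."""
    ls = mp.generate_landscape(extent_cells=(60, 60), n_patches=40, seed=11,
                               barrier_layout=small_layout, field_margins=False)
    ls.validate()
    return ls


@pytest.fixture(scope="session")
def margin_landscape(small_layout):
    """100x100, 150 patches, with carved field margins (study-style variant A)."""
    ls = mp.generate_landscape(extent_cells=(100, 100), n_patches=150, seed=11,
                               barrier_layout=small_layout, field_margins=True)
    ls.validate()
    return ls


@pytest.fixture(scope="session")
def grass_landscape():
    """Single uniform grassland patch (closed population)."""
    return mp.landscape_from_arrays(np.ones((30, 30), int), {1: "grassland"})


@pytest.fixture(scope="session")
def no_barrier_layout():
    return mp.BarrierLayout(road_spacing=0, river=False, n_buildings=0, n_lakes=0)


def make_strip_landscape(gap: int) -> mp.Landscape:
    """Field block and a boundary strip separated by ``gap`` forest cells.

    With gap 0 the strip is adjacent to the field, so field cells within
    the complementation radius can overwinter; with gap > d_w none can.
    """
    grid = np.full((20, 40), 1, dtype=int)
    c = 30
    grid[:, c] = 2
    if gap > 0:
        grid[:, c - gap : c] = 3
        grid[:, c + 1 :] = 3
    types = {1: "rotational_field", 2: "field_boundary", 3: "forest"}
    return mp.landscape_from_arrays(grid, {k: t for k, t in types.items() if (grid == k).any()})


@pytest.fixture(scope="session")
def strip_landscape_factory():
    return make_strip_landscape
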