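import numpy as np
import pytest

from spreadca import RasterLayer, SyntheticSpec, gen_landscape
from spreadca.ca import CellStateGrid, DispersalParams, SuitabilityStack


@pytest.fixture(scope="session")
def small_bundle():
    """A 60x60 landscape at 200 m with the default class composition."""
    return gen_landscape(SyntheticSpec(nx=60, ny=60, seed=42))


@pytest.fixture()
def open_state():
    """A barrier-free 41x41 CA grid at 200 m with one mature central source."""
    state = CellStateGrid.open_grid(41, 41, 200.0)
    state.status[20, 20] = 1
    state.age[20, 20] = 1
    return state


@pytest.fixture()
def full_suitability():
    def make(nrows, ncols, cell_size=200.0):
        return RasterLayer(np.ones((nrows, ncols)), origin_y=nrows * cell_size,
                           cell_size=cell_size)
    return make


def make_stack(suitability, threshold=0.5):
    return SuitabilityStack([(0, suitability)], invasibility_threshold=threshold)


@pytest.fixture()
def default_params():
    return DispersalParams()
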