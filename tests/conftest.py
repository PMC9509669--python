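import numpy as np
import pandas as pd
import pytest

from nichedyn.predictors import SampleMatrix
from nichedyn.raster import GridTransform, RasterGrid
from nichedyn.synthetic_data import SyntheticScenario, gen_env_rasters


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(grid_shape=(60, 100), seed=1, n_native=300, n_intro=300)


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return gen_env_rasters(small_scenario)


@pytest.fixture()
def flat_transform() -> GridTransform:
    return GridTransform(west=-10.0, north=10.0, cellsize=1.0)


@pytest.fixture()
def constant_grid(flat_transform) -> RasterGrid:
    return RasterGrid(np.full((20, 20), 5.0), flat_transform)


def make_matrix(data: dict, group: str = "g") -> SampleMatrix:
    return SampleMatrix(pd.DataFrame(data), group=group)
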