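import numpy as np
import pytest

from fuzzyrisk import FuzzyLayer, GridSpec, RasterLayer, SyntheticConfig, generate


@pytest.fixture
def grid2x2():
    return GridSpec(2, 2)


@pytest.fixture
def single_cell():
    return GridSpec(1, 1)


@pytest.fixture
def masked_grid():
    mask = np.array([[True, True, False], [True, False, True]])
    return GridSpec.from_mask(mask)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def fuzzy_const(grid: GridSpec, value: float, name: str = "f") -> FuzzyLayer:
    return FuzzyLayer(grid, np.full(grid.shape, value), name)


def fuzzy_from(grid: GridSpec, values, name: str = "f") -> FuzzyLayer:
    return FuzzyLayer(grid, np.asarray(values, dtype=float), name)


def raster_from(grid: GridSpec, values, name: str = "r") -> RasterLayer:
    return RasterLayer(grid, np.asarray(values, dtype=float), name)


@pytest.fixture(scope="session")
def small_bundle():
    """One shared small synthetic bundle (30x30, 4 members, 2 scenarios)."""
    from fuzzyrisk.synthetic import ScenarioSpec

    config = SyntheticConfig(
        n_rows=30,
        n_cols=30,
        n_members=4,
        seed=11,
        periods=("early", "late"),
        scenarios=(
            ScenarioSpec("rcp45_fs", 1.0, 1.0),
            ScenarioSpec("rcp85_nfs", 1.7, 1.25),
        ),
    )
    return generate(config)
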