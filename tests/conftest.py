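import numpy as np
import pytest

from vpmgpp.grids import GridGeometry
from vpmgpp.lue import BiomeParameters
from vpmgpp.synthetic import FixtureSpec


@pytest.fixture(scope="session")
def params() -> BiomeParameters:
    return BiomeParameters.from_csv()


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """12 x 12 tile, 3 years — fast variant for unit-level runs."""
    return FixtureSpec(
        seed=7,
        grid=GridGeometry(lon0=10.0, lat0=45.0, cell_size=0.005,
                          n_rows=12, n_cols=12),
    )


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    """The standard study conditions: 50 x 50, 3 years, 25% gaps."""
    return FixtureSpec(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
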