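import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from aerequity.synthetic_city import CityConfig, generate_city


@pytest.fixture(scope="session")
def small_config():
    # 12 km city, two simulated days: big enough to exercise commuting and
    # contiguity, small enough to regenerate quickly
    return CityConfig(
        extent_km=12.0,
        n_blocks=36,
        n_communities=16,
        n_stations=12,
        n_hours=48,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_city(small_config):
    return generate_city(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def square_grid_units():
    """3x3 lattice of unit squares with ids 0..8 (row-major)."""
    rows = []
    for r in range(3):
        for c in range(3):
            rows.append({"unit_id": r * 3 + c, "geometry": box(c, r, c + 1, r + 1)})
    return pd.DataFrame(rows)
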