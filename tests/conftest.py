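import numpy as np
import pandas as pd
import pytest

from forestbpr.table import COLUMNS, PlotTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(n=10, seed=0, **overrides) -> PlotTable:
    """A small well-formed plot table for unit tests."""
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "plot_id": [f"p{i:03d}" for i in range(n)],
            "ecoregion": [f"eco{(i % 3) + 1}" for i in range(n)],
            "mat": r.uniform(0, 20, n),
            "tap": r.uniform(300, 2000, n),
            "aridity": r.uniform(0.1, 1.5, n),
            "soil_cn": r.uniform(8, 25, n),
            "stem_density": r.uniform(200, 2000, n),
            "stand_age": r.uniform(10, 150, n),
            "agb": r.uniform(20, 400, n),
            "richness": r.integers(1, 15, n).astype(float),
        }
    )
    for col, values in overrides.items():
        df[col] = values
    return PlotTable(df[COLUMNS])


@pytest.fixture
def small_table():
    return make_table(n=10)
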