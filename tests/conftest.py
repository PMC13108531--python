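import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from foreststab import layout as layout_mod

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_adult_layout():
    """10x10 grid of 20-m quadrats (200 m x 200 m plot)."""
    return layout_mod.QuadratLayout("small", (0.0, 0.0), 200.0, 200.0, 20.0)


@pytest.fixture
def two_census_adults():
    """Four adults over two censuses: one grower, one static, one death, one recruit."""
    rows = [
        # stem, species, x, y, census, dbh, status
        ("t1", "spA", 30.0, 30.0, 2011, 10.0, "alive"),
        ("t1", "spA", 30.0, 30.0, 2016, 12.0, "alive"),
        ("t2", "spB", 50.0, 60.0, 2011, 5.0, "alive"),
        ("t2", "spB", 50.0, 60.0, 2016, 5.0, "alive"),
        ("t3", "spA", 70.0, 30.0, 2011, 8.0, "alive"),   # absent in 2016 (died)
        ("t4", "spB", 90.0, 90.0, 2016, 2.0, "recruited"),
    ]
    df = pd.DataFrame(rows, columns=["stem_id", "species_id", "x", "y",
                                     "census", "dbh", "status"])
    df["height"] = np.nan
    df["quadrat_id"] = "q0"
    return df
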