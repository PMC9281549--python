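import numpy as np
import pandas as pd
import pytest

from opfe.taxonomy import load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture
def scored_two_outlets():
    """Two tiny outlets: one all-healthy, one mixed, hand-checkable."""
    df = pd.DataFrame(
        {
            "outlet_id": ["A", "A", "B", "B", "B"],
            "meal_id": ["a1", "a2", "b1", "b2", "b3"],
            "category": ["1-2", "1-2", "1-1", "1-1", "1-1"],
            "l": [0, 0, 2, 0, 1],
            "dds": [4, 2, 2, 4, 4],
            "monthly_sales": [10, 5, 3, 4, 2],
        }
    )
    # max-scaling normalization over the whole set: max 1/dds = 1/2
    df["recip_dds_norm"] = (1.0 / df["dds"]) / 0.5
    df["dds_norm"] = df["dds"] / 4.0
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
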