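import numpy as np
import pandas as pd
import pytest

from protistnet import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        {
            "s1": [10, 3, 0, 1],
            "s2": [8, 5, 2, 0],
            "s3": [0, 7, 4, 0],
            "s4": [1, 2, 6, 0],
        },
        index=pd.Index(["o1", "o2", "o3", "o4"], name="otu_id"),
    )
    return OtuTable(counts=counts)


@pytest.fixture
def toy_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "station": ["StA1", "StA1", "StB1", "StB1"],
            "habitat": ["A", "A", "B", "B"],
            "date": ["M1", "M1", "M1", "M1"],
            "replicate": ["1", "2", "1", "2"],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
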