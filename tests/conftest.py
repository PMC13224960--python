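import numpy as np
import pandas as pd
import pytest

import omicnet as on


@pytest.fixture
def toy_table():
    """3 features x 4 samples, hand-enterable numbers."""
    return on.OmicsTable(
        values=pd.DataFrame(
            [[1.0, 2.0, 0.0, 4.0],
             [0.0, 3.0, 1.0, 0.0],
             [2.0, 0.0, 0.0, 1.0]],
            index=["f1", "f2", "f3"],
            columns=["s1", "s2", "s3", "s4"],
        ),
        layer="micro",
    )


@pytest.fixture
def small_net():
    """5 nodes, 4 attributed edges."""
    return on.net_from_edgelist([
        ("a", "b", 0.7, 0.01),
        ("b", "c", -0.65, 0.02),
        ("c", "d", 0.8, 0.001),
        ("d", "e", 0.5, 0.04),
    ])


@pytest.fixture(scope="session")
def seeded_block_table():
    return on.planted_block_data(
        n_features=100, n_samples=50, n_blocks=5, within_r=0.7, seed=1)
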