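import numpy as np
import pandas as pd
import pytest

from digestnet.datatypes import AbundanceTable


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 ASVs x 4 samples, two configurations, known counts."""
    counts = pd.DataFrame(
        [[5, 0, 2, 1], [1, 1, 1, 1], [0, 10, 0, 3]],
        index=["a1", "a2", "a3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    dates = pd.Series(
        ["2017-01-01", "2017-01-15", "2017-01-29", "2017-02-12"],
        index=counts.columns,
    )
    config = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return AbundanceTable(counts, dates, config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
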