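import numpy as np
import pandas as pd
import pytest

from dcmkit.dcm import AbundanceSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """A hand-sized barcode count table (3 barcodes x 4 timepoints)."""
    return pd.DataFrame(
        {
            0.0: [30, 10, 0],
            1.0: [20, 20, 10],
            2.0: [10, 30, 20],
            3.0: [5, 40, 30],
        },
        index=["ACGTACGTACGTACG", "TTTTACGTACGTACG", "GGGGACGTACGTACG"],
    )


def make_series(values, timestamps=None, kind="absolute"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if timestamps is None:
        timestamps = np.arange(values.shape[1], dtype=float)
    ids = [f"m{i}" for i in range(values.shape[0])]
    return AbundanceSeries(ids, timestamps, values, kind=kind)
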