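import numpy as np
import pandas as pd
import pytest

from trialwise import EpochSet


def make_epochs(data, fs=500.0, t0=-200.0, channels=None, table=None, **prov):
    """Build a small EpochSet around a raw array, filling in defaults."""
    data = np.asarray(data, float)
    n, c, t = data.shape
    channels = channels or [f"ch{i}" for i in range(c)]
    step = 1000.0 / fs
    times = t0 + step * np.arange(t)
    table = table if table is not None else pd.DataFrame({"trial": np.arange(n)})
    return EpochSet(data, channels, times, fs, table, prov)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """20 trials x 3 channels x 46 samples at 100 Hz, -200..700 ms."""
    return make_epochs(rng.normal(size=(20, 3, 91)), fs=100.0)
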