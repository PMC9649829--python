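import numpy as np
import pandas as pd
import pytest

from uhrsleepwm import JHU_LABELS, RestInterval


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def rest_8h():
    return RestInterval(pd.Timestamp("2024-03-01 22:30"),
                        pd.Timestamp("2024-03-02 06:30"))


@pytest.fixture
def roi_row(rng):
    """One full 48-ROI FA row as a dict."""
    return dict(zip(JHU_LABELS, rng.uniform(0.3, 0.8, size=48)))


def make_recording(counts, bed="2024-03-01 23:00", pad_before=5, pad_after=5,
                   pad_value=0.0):
    """Recording whose in-bed epochs carry *counts*, padded outside the interval."""
    counts = np.asarray(counts, dtype=float)
    from uhrsleepwm import ActigraphyRecording

    bed = pd.Timestamp(bed)
    rise = bed + pd.Timedelta(minutes=len(counts))
    start = bed - pd.Timedelta(minutes=pad_before)
    total = pad_before + len(counts) + pad_after
    epochs = pd.date_range(start, periods=total, freq="1min")
    full = np.full(total, pad_value)
    full[pad_before:pad_before + len(counts)] = counts
    return ActigraphyRecording(epochs=epochs, counts=full,
                               rest=RestInterval(bed, rise))
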