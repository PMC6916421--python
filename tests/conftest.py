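import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import acmkit as ak

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def control_recording():
    """One simulated healthy-control week (fixed seed)."""
    return ak.generate_subject(ak.phenotype_presets()["control"], days=7, seed=42)


@pytest.fixture(scope="session")
def control_epoched(control_recording):
    """The control week on the 30-s grid with TAP and sleep columns."""
    epoched = ak.to_common_grid(control_recording, 30)
    ak.add_tap(epoched)
    ak.add_sleep(epoched)
    return epoched


def make_epoched(values, epoch_length, channel="x", subject_id="toy"):
    """EpochedRecording straight from an array of whole-day values."""
    values = np.asarray(values, dtype=float)
    p = 86_400 // epoch_length
    assert values.size % p == 0
    index = pd.date_range("2024-01-01", periods=values.size, freq=f"{epoch_length}s")
    data = pd.DataFrame({channel: values}, index=index)
    return ak.EpochedRecording(subject_id, epoch_length, data)


@pytest.fixture
def square_tap_epoched():
    """Two days of TAP at 0.15 during 00:00-08:00 and 0.60 otherwise (30-min epochs)."""
    p = 48
    day = np.where(np.arange(p) < 16, 0.15, 0.60)
    return make_epoched(np.tile(day, 2), 1800, channel="tap")
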