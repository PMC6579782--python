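import numpy as np
import pytest

from emodoc.montage import standard_montage
from emodoc.preprocessing import EpochSet
from emodoc.synth import Recording, EventSequence


@pytest.fixture(scope="session")
def montage_small():
    """Four scalp channels plus mastoids: cheap but fully featured."""
    return standard_montage(("F3", "F4", "O1", "O2"))


@pytest.fixture(scope="session")
def montage_full():
    return standard_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(montage, data, rate=500.0, onsets=(), labels=()):
    events = EventSequence(np.asarray(onsets, dtype=np.int64), tuple(labels))
    return Recording(np.asarray(data, dtype=float), rate, montage, events)


def make_epochs(montage, data, rate=500.0, labels=None, t0_ms=-200.0, baseline=None):
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_t = data.shape
    assert n_ch == montage.n_channels
    times = t0_ms + np.arange(n_t) * 1000.0 / rate
    if labels is None:
        labels = ("neutral",) * n_trials
    return EpochSet(data, times, tuple(labels), rate, montage, baseline)
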