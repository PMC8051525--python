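import numpy as np
import pytest

from eegfx import EEGRecord, extract_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def record_4lead(rng):
    """4 leads x 10 s of mixed noise + oscillation at 250 Hz."""
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    data = np.vstack([
        10 * rng.standard_normal(t.size) + 3 * np.sin(2 * np.pi * 10 * t),
        8 * rng.standard_normal(t.size),
        5 * rng.standard_normal(t.size) + 2 * np.sin(2 * np.pi * 5 * t),
        12 * rng.standard_normal(t.size),
    ])
    return EEGRecord(data, fs=fs, lead_labels=("A", "B", "C", "D"),
                     subject_id="S01")


def make_epoch(samples, fs=250.0, labels=None):
    samples = np.atleast_2d(np.asarray(samples, float))
    if labels is None:
        labels = tuple(str(i + 1) for i in range(samples.shape[0]))
    rec = EEGRecord(samples, fs=fs, lead_labels=labels)
    return extract_epoch(rec, 0.0, rec.duration)


@pytest.fixture
def epoch_factory():
    return make_epoch
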