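import numpy as np
import pytest

from mstates import SyntheticSpec, generate_subject


@pytest.fixture(scope="session")
def synth_subject():
    """One standard synthetic subject: 64 ch, 4 maps, 20 s at 250 Hz, SNR 5."""
    return generate_subject(SyntheticSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def switch_distance_mask(sequence, fs, min_ms=10.0):
    """Samples at least ``min_ms`` away from any state switch (or edge)."""
    sequence = np.asarray(sequence)
    n = len(sequence)
    boundaries = np.flatnonzero(np.r_[True, sequence[1:] != sequence[:-1], True])
    dist = np.full(n, np.inf)
    idx = np.arange(n)
    for b in boundaries:
        dist = np.minimum(dist, np.abs(idx - b))
        dist = np.minimum(dist, np.abs(idx - (b - 1)))
    return dist >= min_ms * fs / 1000.0
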