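"""Synthetic resting-state EEG with known microstate structure.

The generator emulates the standard microstate picture of eyes-open rest:
the scalp field is, at any instant, one of a small number of fixed
topographies whose amplitude is modulated by an alpha-band carrier, with
the active topography switching every few tens to hundreds of
milliseconds.  Dwell times are gamma-distributed (a semi-Markov process),
so the switching sequence is deliberately *not* Markovian — the regime the
microstate Lempel–Ziv complexity measure is designed to be sensitive to.
Sensor noise is i.i.d. Gaussian, scaled to a requested signal-to-noise
ratio (RMS signal / RMS noise).

Every ground truth (topographies, per-sample state sequence) is returned
alongside the recording so clustering, backfitting, sequence statistics
and complexity can all be validated without any external dataset.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io import CLINICAL_19
from .recording import EEGRecording, ParameterError

# smoothing kernel applied along the electrode axis so maps are spatially
# coherent rather than white; binomial weights
_SMOOTH = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Defaults follow the study conditions this package targets: 64-channel
    eyes-open rest, 20 s epochs, four microstate classes with ~60 ms mean
    dwell, alpha (10 Hz) amplitude carrier and SNR 5.
    """

    n_channels: int = 64
    k_true: int = 4
    fs: float = 250.0
    duration_s: float = 20.0
    dwell_mean_ms: float = 60.0
    dwell_shape: float = 2.0
    transition_weights: np.ndarray | None = None  # k x k, zero diagonal
    snr: float = 5.0
    carrier_hz: float = 10.0
    amplitude_uv: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ParameterError("k_true must be at least 2")
        if not self.snr > 0:
            raise ParameterError("snr must be positive")
        if self.transition_weights is not None:
            w = np.asarray(self.transition_weights, dtype=float)
            if w.shape != (self.k_true, self.k_true):
                raise ParameterError("transition_weights must be k_true x k_true")
            if np.any(np.diag(w) != 0):
                raise ParameterError("transition_weights must have a zero diagonal")
            if np.any(w < 0):
                raise ParameterError("transition_weights must be nonnegative")
            self.transition_weights = w

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclasses.dataclass
class SyntheticGroundTruth:
    """Topographies, state sequence and the recording they generated."""

    maps: np.ndarray            # (k_true, n_channels), unit-norm, zero-mean
    state_sequence: np.ndarray  # per-sample labels in 0..k_true-1
    recording: EEGRecording
    spec: SyntheticSpec


def default_labels(n_channels: int) -> list:
    """Channel names: the clinical 10-20 set for 19 channels, generic otherwise."""
    if n_channels == len(CLINICAL_19):
        return list(CLINICAL_19)
    return [f"CH{i + 1:02d}" for i in range(n_channels)]


def generate_maps(n_channels: int, k: int, seed=None) -> np.ndarray:
    """Draw ``k`` distinct unit-norm zero-mean topographies.

    Random directions are orthonormalized and then smoothed along the
    electrode axis; smoothing introduces mild correlations, so candidates
    are redrawn until every pairwise |spatial correlation| is below 0.5.
    """
    if k >= n_channels:
        raise ParameterError("need k < n_channels")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        g = rng.standard_normal((n_channels, k))
        q, _ = np.linalg.qr(g)
        maps = np.empty((k, n_channels))
        for j in range(k):
            v = np.convolve(q[:, j], _SMOOTH, mode="same")
            v = v - v.mean()
            maps[j] = v / np.linalg.norm(v)
        corr = maps @ maps.T
        np.fill_diagonal(corr, 0.0)
        if np.abs(corr).max() < 0.5:
            return maps
    raise RuntimeError("could not draw sufficiently distinct topographies")


def generate_sequence(spec: SyntheticSpec, rng=None) -> np.ndarray:
    """Draw a per-sample state sequence from the semi-Markov model.

    Dwell times (ms) are gamma(shape, mean/shape) distributed, rounded to
    at least one sample; successors are drawn from the renormalized row of
    ``transition_weights`` (uniform over the other states by default).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = spec.k_true
    w = spec.transition_weights
    if w is None:
        w = np.ones((k, k)) - np.eye(k)
    rows = w.sum(axis=1)
    if np.any(rows <= 0):
        raise ParameterError("every transition_weights row needs a nonzero entry")
    probs = w / rows[:, None]

    n = spec.n_samples
    labels = np.empty(n, dtype=np.int64)
    state = int(rng.integers(k))
    pos = 0
    scale = spec.dwell_mean_ms / spec.dwell_shape
    while pos < n:
        dwell_ms = rng.gamma(spec.dwell_shape, scale)
        n_dwell = max(1, int(round(dwell_ms * spec.fs / 1000.0)))
        labels[pos : pos + n_dwell] = state
        pos += n_dwell
        state = int(rng.choice(k, p=probs[state]))
    return labels


def generate_eeg(
    maps: np.ndarray, sequence: np.ndarray, spec: SyntheticSpec,
    rng=None, subject_id: str = "", group: str = "unknown",
) -> SyntheticGroundTruth:
    """Render a recording: carrier-modulated active map plus sensor noise.

    The instantaneous field is ``a(t) * maps[state(t)]`` where ``a`` is a
    ``carrier_hz`` sinusoid whose phase is re-randomized at every state
    switch; i.i.d. Gaussian noise (average-referenced) is added so that
    RMS(signal)/RMS(noise) equals ``spec.snr`` exactly.
    """
    maps = np.asarray(maps, dtype=float)
    sequence = np.asarray(sequence)
    if maps.shape[0] != spec.k_true:
        raise ParameterError("len(maps) must equal spec.k_true")
    if sequence.min() < 0 or sequence.max() >= spec.k_true:
        raise ParameterError("sequence labels outside 0..k_true-1")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)

    n = len(sequence)
    t = np.arange(n) / spec.fs
    amp = np.empty(n)
    boundaries = np.flatnonzero(np.r_[True, sequence[1:] != sequence[:-1], True])
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        amp[s:e] = np.sin(2.0 * math.pi * spec.carrier_hz * t[s:e] + phase)
    signal = spec.amplitude_uv * (maps[sequence] * amp[:, None]).T  # (p, n)

    if math.isfinite(spec.snr):
        noise = rng.standard_normal(signal.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        rms_s = math.sqrt(float(np.mean(signal**2)))
        rms_n = math.sqrt(float(np.mean(noise**2)))
        data = signal + (rms_s / (spec.snr * rms_n)) * noise
    else:
        data = signal
    data = data - data.mean(axis=0, keepdims=True)
    rec = EEGRecording(data, spec.fs, default_labels(spec.n_channels),
                       subject_id=subject_id, group=group)
    return SyntheticGroundTruth(maps, sequence, rec, spec)


def generate_subject(spec: SyntheticSpec, maps: np.ndarray | None = None,
                     subject_id: str = "", group: str = "unknown") -> SyntheticGroundTruth:
    """Convenience: maps + sequence + recording from one spec/seed."""
    rng = np.random.default_rng(spec.seed)
    if maps is None:
        maps = generate_maps(spec.n_channels, spec.k_true, rng)
    seq = generate_sequence(spec, rng)
    return generate_eeg(maps, seq, spec, rng, subject_id=subject_id, group=group)


def generate_feature_cohort(n_per_group: dict, means: dict, sds: dict,
                            seed=None) -> pd.DataFrame:
    """Draw Gaussian (θRP, C) feature points per group for classifier tests.

    ``n_per_group``, ``means`` and ``sds`` are dicts keyed by group name;
    means and sds are (θRP, C) pairs.  Returns a tidy frame with columns
    ``subject_id, group, theta_rp, C``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in n_per_group.items():
        if n <= 0:
            raise ParameterError(f"group {grp!r}: n must be positive")
        mu = np.asarray(means[grp], dtype=float)
        sd = np.asarray(sds[grp], dtype=float)
        if np.any(sd <= 0):
            raise ParameterError(f"group {grp!r}: sds must be positive")
        pts = rng.normal(mu, sd, size=(n, 2))
        for i, (trp, c) in enumerate(pts):
            rows.append((f"{grp}_{i + 1:03d}", grp, trp, c))
    return pd.DataFrame(rows, columns=["subject_id", "group", "theta_rp", "C"])
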