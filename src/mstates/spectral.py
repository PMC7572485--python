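"""Spectral features: theta relative power.

Theta relative power (θRP) — power in the theta band as a fraction of
broadband power — is a standard proxy for the spectral slowing of the EEG
in dementia; here it is the single spectral feature combined with
microstate complexity in the classifier.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .recording import EEGRecording, LengthError, ParameterError


@dataclasses.dataclass
class SpectralFeature:
    """θRP with the band edges that produced it."""

    theta_rp: float
    band_edges: tuple          # (theta_low, theta_high, total_low, total_high) Hz
    per_channel: np.ndarray | None = None


def _band_power(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> np.ndarray:
    """Trapezoidal band power with interpolated band-edge points.

    Including interpolated PSD values at the exact band edges makes the
    integral additive over a partition of the total band (shared edges
    cancel), so relative powers over a partition sum to one.
    """
    inside = (freqs > low) & (freqs < high)
    f = np.concatenate(([low], freqs[inside], [high]))
    p_lo = np.array([np.interp(low, freqs, ch) for ch in psd])
    p_hi = np.array([np.interp(high, freqs, ch) for ch in psd])
    p = np.column_stack([p_lo, psd[:, inside], p_hi])
    return np.trapezoid(p, f, axis=1)


def theta_relative_power(
    rec: EEGRecording,
    theta=(4.0, 8.0),
    total=(1.0, 30.0),
    seg_seconds: float = 2.0,
) -> SpectralFeature:
    """θRP: integrated theta power over integrated broadband power.

    The PSD is estimated per channel by Welch's method (2 s Hamming
    segments, 50% overlap); band integrals are trapezoidal over frequency
    bins with interpolated band edges.  The scalar feature is the mean
    over channels; per-channel values are retained for inspection.
    """
    t_lo, t_hi = theta
    b_lo, b_hi = total
    if not (b_lo <= t_lo < t_hi <= b_hi):
        raise ParameterError("theta band must lie within the total band")
    if rec.fs <= 2 * b_hi:
        raise ParameterError(
            f"total band upper edge {b_hi} Hz at or above Nyquist ({rec.fs / 2} Hz)"
        )
    if rec.duration_s < 2 * seg_seconds:
        raise LengthError(
            f"need at least {2 * seg_seconds} s for Welch segments of {seg_seconds} s"
        )
    nperseg = int(round(seg_seconds * rec.fs))
    freqs, psd = signal.welch(
        rec.data, fs=rec.fs, window="hamming",
        nperseg=nperseg, noverlap=nperseg // 2, axis=1,
    )
    num = _band_power(freqs, psd, t_lo, t_hi)
    den = _band_power(freqs, psd, b_lo, b_hi)
    per_channel = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return SpectralFeature(
        theta_rp=float(per_channel.mean()),
        band_edges=(t_lo, t_hi, b_lo, b_hi),
        per_channel=per_channel,
    )
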