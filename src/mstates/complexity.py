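"""Lempel–Ziv complexity of microstate sequences and comparison measures.

The central measure, C, applies the 1976 Lempel–Ziv exhaustive-history
parse to the microstate *transition* sequence (maximal constant runs
collapsed to single symbols): C counts the number of distinct words
encountered reading left to right, so repetitive transition patterns give
low C and rich, non-Markovian transitioning gives high C.  Because it
operates on the symbolic sequence, C makes no stationarity or
Markovianity assumption.

Two classical comparison measures are provided: Ω-complexity (the
effective number of independent spatial components, from the entropy of
the channel-covariance eigenspectrum) and the time-series LZC used in the
earlier EEG literature (median-binarized single channels, averaged).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cluster import LabelSequence
from .recording import EEGRecording, ParameterError, ensure_average_reference


def lz76_complexity(symbols) -> int:
    """LZ76 word count of a symbol sequence (exhaustive history parse).

    Scanning left to right, the current word is extended while it can be
    reproduced from the extended prior history (self-overlapping copies
    allowed); when extension fails the word — including the failing
    symbol — is closed and a new one starts.  The terminal word counts
    even if still reproducible.  Conventions: the empty sequence has
    complexity 0 and a single symbol has complexity 1.
    """
    seq = list(symbols)
    n = len(seq)
    if n == 0:
        return 0
    codes = {}
    for sym in seq:
        if sym not in codes:
            codes[sym] = len(codes)
    s = "".join(chr(codes[sym]) for sym in seq)
    c = 0
    h = 0
    while h < n:
        j = h + 1
        while j < n and s.find(s[h:j], 0, j - 1) != -1:
            j += 1
        c += 1
        h = j
    return c


def collapse_runs(labels) -> np.ndarray:
    """Replace each maximal constant run by a single symbol."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return labels
    keep = np.r_[True, labels[1:] != labels[:-1]]
    return labels[keep]


def microstate_lzc(seq, collapse: bool = True, normalize: bool = False) -> float:
    """Microstate LZC, C: LZ76 complexity of the transition sequence.

    With ``collapse`` (default) the per-sample sequence is first reduced
    to its transition sequence, making C insensitive to the sampling
    rate; without it, dwell lengths also contribute.  With ``normalize``
    the word count is multiplied by ``log_k(n) / n`` (n symbols, alphabet
    size k observed), giving values near 1 for random sequences.  A
    single-class sequence collapses to one symbol and returns C = 1 (the
    degenerate minimum); normalization is undefined there and skipped.
    """
    labels = seq.labels if isinstance(seq, LabelSequence) else np.asarray(seq)
    if len(labels) == 0:
        raise ParameterError("empty label sequence")
    sym = collapse_runs(labels) if collapse else labels
    c = lz76_complexity(sym)
    if normalize:
        n = len(sym)
        k = len(np.unique(sym))
        if k < 2 or n < 2:
            return float(c)
        return float(c) * math.log(n, k) / n
    return float(c)


def timeseries_lzc(rec: EEGRecording) -> float:
    """Classical per-channel binary LZC, averaged over channels.

    Each channel is binarized at its median (scale-free), parsed with
    LZ76, and normalized by ``n / log2(n)``; the mean over channels is
    returned.  A constant channel binarizes to the all-zeros string
    (complexity 2 for n >= 2) and is included as such.
    """
    data = rec.data
    if data.shape[1] < 2:
        raise ParameterError("need at least 2 samples")
    n = data.shape[1]
    norm = math.log2(n) / n
    vals = []
    for ch in data:
        binary = (ch > np.median(ch)).astype(np.uint8)
        vals.append(lz76_complexity(binary.tobytes()) * norm)
    return float(np.mean(vals))


def omega_complexity(rec: EEGRecording) -> float:
    """Ω-complexity: effective number of independent spatial components.

    The eigenvalues of the channel covariance are normalized to a
    probability distribution and Ω = exp(entropy).  Rank-1 data (a single
    topography waxing and waning) gives Ω = 1; N uncorrelated
    equal-variance channels approach Ω = N (N - 1 after average
    referencing).
    """
    rec = ensure_average_reference(rec)
    if rec.n_samples <= rec.n_channels:
        raise ParameterError("need more samples than channels")
    cov = np.cov(rec.data)
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ParameterError("recording has zero variance")
    lam = eig / total
    lam = lam[lam > 1e-12]
    return float(np.exp(-np.sum(lam * np.log(lam))))


@dataclasses.dataclass
class ComplexityResult:
    """The complexity panel for one recording/sequence."""

    C: float
    C_norm: float
    omega: float
    ts_lzc: float
    collapse: bool = True


def complexity_profile(rec: EEGRecording, seq, collapse: bool = True) -> ComplexityResult:
    """Compute C, normalized C, Ω and time-series LZC together."""
    return ComplexityResult(
        C=microstate_lzc(seq, collapse=collapse, normalize=False),
        C_norm=microstate_lzc(seq, collapse=collapse, normalize=True),
        omega=omega_complexity(rec),
        ts_lzc=timeseries_lzc(rec),
        collapse=collapse,
    )
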