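"""Reading, preprocessing and reformatting of multichannel EEG.

Supports EDF (the clinical standard for routine 19-channel EEG) through
mne, and plain delimited-text channel-by-sample matrices.  A minimal EDF
writer is included so synthetic recordings can be exported in the clinical
format; it covers plain continuous EDF with one-second data records, which
is all this package produces.

The preprocessing chain is the standard microstate one: zero-phase
band-pass (4th-order Butterworth, 1–30 Hz by default), common-average
reference, optional polyphase resampling, and selection of the first
``epoch_length_s`` seconds.  Everything is configurable.
"""

from __future__ import annotations

import json
import math
import struct
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import (
    EEGRecording,
    FormatError,
    LengthError,
    MetadataError,
    ParameterError,
)

#: The 19-channel 10-20 montage used by routine clinical EEG systems.
CLINICAL_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
            if isinstance(meta, dict):
                return meta
        except (json.JSONDecodeError, OSError):
            pass
    return {}


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV).

    Channel labels and sampling rate come from the EDF header; a JSON
    sidecar next to the file (same stem, ``.json``) may supply
    ``subject_id`` and ``group``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of parse errors
        raise FormatError(f"could not parse {path.name} as EDF: {exc}") from exc
    labels = list(raw.ch_names)
    if not labels or any(not l.strip() for l in labels):
        raise MetadataError(f"{path.name}: missing channel labels in EDF header")
    data_uv = raw.get_data() * 1e6  # mne returns SI volts
    meta = _read_sidecar(path)
    return EEGRecording(
        data_uv, float(raw.info["sfreq"]), labels,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "unknown")),
    )


def _fmt8(x: float) -> bytes:
    s = f"{x:.6g}"
    if len(s) > 8:
        s = f"{x:.3g}"
    return s[:8].ljust(8).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as plain continuous EDF (16-bit, 1 s records).

    Requires an integer sampling rate; the last partial second, if any,
    is zero-padded to a whole data record.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ParameterError("EDF export requires an integer sampling rate")
    n_sig = rec.n_channels
    n_rec = max(1, math.ceil(rec.n_samples / fs))
    data = np.zeros((n_sig, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b""
    header += b"0".ljust(8)
    header += rec.subject_id[:80].ljust(80).encode("ascii", "replace")
    header += b"Startdate 01-JAN-2000".ljust(80)
    header += b"01.01.00"
    header += b"00.00.00"
    header += str(256 * (1 + n_sig)).ljust(8).encode("ascii")
    header += b" " * 44
    header += str(n_rec).ljust(8).encode("ascii")
    header += b"1".ljust(8)
    header += str(n_sig).ljust(4).encode("ascii")

    def field(values, width):
        return b"".join(str(v)[:width].ljust(width).encode("ascii") for v in values)

    header += field(rec.labels, 16)
    header += field([""] * n_sig, 80)                     # transducer
    header += field(["uV"] * n_sig, 8)                    # physical dimension
    header += b"".join(_fmt8(v) for v in pmin)
    header += b"".join(_fmt8(v) for v in pmax)
    header += field([dmin] * n_sig, 8)
    header += field([dmax] * n_sig, 8)
    header += field([""] * n_sig, 80)                     # prefiltering
    header += field([fs] * n_sig, 8)                      # samples per record
    header += field([""] * n_sig, 32)                     # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(struct.pack(f"<{block.size}h", *block.ravel()))


def read_matrix_text(path, fs: float, labels, delimiter=None) -> EEGRecording:
    """Read a delimited numeric table (one row per channel) as a recording.

    With ``delimiter=None`` the separator is sniffed from the first line
    (comma, tab, or whitespace).
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "," if "," in first else ("\t" if "\t" in first else None)
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric table: {exc}") from exc
    if not np.isfinite(data).all():
        raise FormatError(f"{path.name}: table contains non-finite values")
    labels = list(labels)
    if data.shape[0] != len(labels):
        raise MetadataError(
            f"{path.name}: {data.shape[0]} rows but {len(labels)} channel labels"
        )
    meta = _read_sidecar(path)
    return EEGRecording(
        data, fs, labels,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=str(meta.get("group", "unknown")),
    )


def write_matrix_text(rec: EEGRecording, path, delimiter=",") -> None:
    np.savetxt(path, rec.data, delimiter=delimiter)


def _resample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if abs(target_fs - fs) < 1e-12:
        return data
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def preprocess(
    rec: EEGRecording,
    band=(1.0, 30.0),
    target_fs=None,
    epoch_length_s=20.0,
    order: int = 4,
) -> EEGRecording:
    """Band-pass, average-reference, optionally resample and epoch.

    Filtering is zero-phase (forward-backward Butterworth of the given
    order), so no phase distortion enters the topographic time courses.
    When the recording is longer than ``epoch_length_s`` only the first
    epoch is retained; shorter recordings raise :class:`LengthError`.
    Pass ``epoch_length_s=None`` to keep the full length.
    """
    low, high = band
    if not (0 < low < high < rec.fs / 2):
        raise ParameterError(
            f"band {band} must satisfy 0 < low < high < fs/2 = {rec.fs / 2}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    fs = rec.fs
    if target_fs is not None:
        data = _resample(data, fs, target_fs)
        fs = float(target_fs)
    if epoch_length_s is not None:
        n_epoch = int(round(epoch_length_s * fs))
        if data.shape[1] < n_epoch:
            raise LengthError(
                f"recording has {data.shape[1] / fs:.2f} s but "
                f"{epoch_length_s} s requested"
            )
        data = data[:, :n_epoch]
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(data, fs, list(rec.labels), rec.subject_id, rec.group)


def downsample_to_clinical(
    rec: EEGRecording, target_labels=CLINICAL_19, target_fs: float = 512.0
) -> EEGRecording:
    """Restrict to a clinical montage and resample to a clinical rate.

    Emulates converting research-grade EEG (e.g. 64 channels at 1000 Hz)
    to the 19-channel format of routine clinical systems so that features
    computed on both are comparable.  Channels are reordered to
    ``target_labels``, resampled, then re-referenced to the average of the
    retained channels.
    """
    target_labels = list(target_labels)
    missing = [l for l in target_labels if l not in rec.labels]
    if missing:
        raise MetadataError(f"channels absent from recording: {missing}")
    if target_fs > rec.fs:
        raise ParameterError("target_fs must not exceed the recording rate")
    idx = [rec.labels.index(l) for l in target_labels]
    data = _resample(rec.data[idx], rec.fs, target_fs)
    data = data - data.mean(axis=0, keepdims=True)
    return EEGRecording(data, float(target_fs), target_labels,
                        rec.subject_id, rec.group)
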