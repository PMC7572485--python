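"""Container for multichannel EEG and referencing utilities.

All voltages in this package are in microvolts (µV) and all recordings are
stored as a ``channels x samples`` matrix.  Resting-state EEG is analysed
against the common average reference, i.e. the mean over channels at every
sample is zero; most downstream operations (topographic clustering, global
field power, Ω-complexity) assume this and re-reference defensively.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

#: Canonical cohort labels: healthy older adults, Alzheimer's disease,
#: stable MCI, MCI-to-AD converters, or unlabelled.
GROUPS = ("HOA", "AD", "MCIs", "MCIc", "unknown")


class FormatError(ValueError):
    """A file or array could not be interpreted in its declared format."""


class MetadataError(ValueError):
    """Channel labels or other metadata are inconsistent with the data."""


class ParameterError(ValueError):
    """An argument is outside its valid domain."""


class LengthError(ValueError):
    """A recording is too short for the requested operation."""


@dataclasses.dataclass
class EEGRecording:
    """A ``channels x samples`` voltage matrix with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in µV, one row per channel.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Ordered channel names (10-20 system for clinical montages).
    subject_id : str
        Free-form subject identifier.
    group : str
        Cohort label; conventionally one of :data:`GROUPS`.
    """

    data: np.ndarray
    fs: float
    labels: list
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("data must be a 2-D channels x samples matrix")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise MetadataError(
                f"{len(self.labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")
        self.fs = float(self.fs)
        if not np.isfinite(self.data).all():
            raise FormatError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.fs, list(self.labels),
            self.subject_id, self.group,
        )

    def average_reference(self) -> "EEGRecording":
        """Return a copy re-referenced to the common average."""
        out = self.copy()
        out.data -= out.data.mean(axis=0, keepdims=True)
        return out

    def is_average_referenced(self, tol: float = 1e-9) -> bool:
        if self.n_samples == 0:
            return True
        return bool(np.abs(self.data.mean(axis=0)).max() <= tol)


def ensure_average_reference(rec: EEGRecording, tol: float = 1e-6) -> EEGRecording:
    """Return ``rec`` average-referenced, warning if it was not already."""
    if rec.is_average_referenced(tol):
        return rec
    warnings.warn(
        "recording is not average-referenced; re-referencing automatically",
        stacklevel=3,
    )
    return rec.average_reference()
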