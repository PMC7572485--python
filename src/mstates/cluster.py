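"""Microstate extraction: polarity-invariant clustering, class-number
selection, cohort-level clustering, map alignment and backfitting.

Topographic maps are equivalent under sign inversion, so clustering uses
the squared spatial Pearson correlation: the distance between an observed
topography ``x`` and a map ``m`` is ``1 - r(x, m)**2``.  Cluster centroids
are updated as the first principal eigenvector of the members' outer
product sum (the direction maximizing explained variance irrespective of
polarity) — the "modified k-means" standard in the microstate literature.
The number of classes is chosen with the Krzanowski–Lai criterion on the
within-cluster dispersion curve.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin

from .recording import EEGRecording, MetadataError, ParameterError, ensure_average_reference


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    """Demean and unit-normalize each row (average-reference convention)."""
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def gfp_curve(rec: EEGRecording):
    """Global field power and its strict local maxima.

    GFP(t) is the spatial standard deviation over channels of the
    average-referenced voltages at sample t; its peaks are the moments of
    highest topographic signal-to-noise, conventionally used as the
    clustering observations.
    """
    rec = ensure_average_reference(rec)
    gfp = rec.data.std(axis=0, ddof=0)
    interior = (gfp[1:-1] > gfp[:-2]) & (gfp[1:-1] > gfp[2:])
    peaks = np.flatnonzero(interior) + 1
    return gfp, peaks


def gfp_peak_maps(rec: EEGRecording) -> np.ndarray:
    """Topographies at GFP peaks as an observations x channels matrix."""
    _, peaks = gfp_curve(rec)
    if len(peaks) == 0:
        raise ParameterError("recording has no GFP peaks")
    return rec.data.T[peaks]


@dataclasses.dataclass
class MicrostateModel:
    """An ordered set of unit-norm microstate maps with fit diagnostics."""

    maps: np.ndarray            # (k, n_channels), unit-norm, zero-mean rows
    gev: float                  # global explained variance in [0, 1]
    level: str = "subject"      # "subject" or "cohort"
    channel_labels: list | None = None
    names: list | None = None   # e.g. ["A", "B", "C", "D"] once assigned

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclasses.dataclass
class LabelSequence:
    """Per-sample microstate class labels (0-based) for one recording."""

    labels: np.ndarray
    fs: float
    n_classes: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.n_classes == 0:
            self.n_classes = int(self.labels.max()) + 1 if len(self.labels) else 0

    def __len__(self) -> int:
        return len(self.labels)


def runs_of(labels: np.ndarray):
    """Maximal constant runs as (start, length, label) triples."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    edges = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1], True])
    return [
        (int(s), int(e - s), int(labels[s]))
        for s, e in zip(edges[:-1], edges[1:])
    ]


class ModifiedKMeans(BaseEstimator, ClusterMixin):
    """Polarity-invariant k-means over topographic observations.

    Parameters
    ----------
    n_clusters : int
        Number of microstate classes k.
    n_init : int
        Independent k-means++ restarts; the restart with the highest
        global explained variance (GEV) wins.
    max_iter : int
        Iteration cap per restart (convergence is normally a label
        fixpoint within a few tens of iterations).
    tol : float
        Alternative convergence test: stop when GEV improves by less.
    random_state : int or None
        Seed; fixed seeds give bit-reproducible fits.

    Attributes
    ----------
    maps_ : ndarray (n_clusters, n_channels)
        Unit-norm, zero-mean cluster maps.
    labels_ : ndarray (n_observations,)
        Assigned class per observation (argmax squared correlation).
    gev_ : float
        GEV of the training observations,
        ``sum((gfp_t * r_t)**2) / sum(gfp_t**2)``.
    dispersion_ : float
        Within-cluster dispersion ``W = sum(1 - r_t**2)`` (the quantity
        penalized by the Krzanowski–Lai criterion).
    """

    def __init__(self, n_clusters=4, n_init=20, max_iter=300, tol=1e-7,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _kpp_seed(Xn: np.ndarray, k: int, rng) -> np.ndarray:
        """k-means++ seeding with d = 1 - r**2 as the squared distance."""
        n = Xn.shape[0]
        chosen = [int(rng.integers(n))]
        d = 1.0 - (Xn @ Xn[chosen[0]]) ** 2
        for _ in range(1, k):
            w = np.clip(d, 0.0, None)
            total = w.sum()
            j = int(rng.choice(n, p=w / total)) if total > 0 else int(rng.integers(n))
            chosen.append(j)
            d = np.minimum(d, 1.0 - (Xn @ Xn[j]) ** 2)
        return Xn[chosen].copy()

    @staticmethod
    def _principal_map(members: np.ndarray) -> np.ndarray:
        s = members.T @ members
        _, vecs = np.linalg.eigh(s)
        m = vecs[:, -1]
        m = m - m.mean()          # stays in the average-reference subspace
        norm = np.linalg.norm(m)
        return m / norm if norm > 0 else vecs[:, -1]

    def _fit_once(self, Xn, gfp2, rng):
        k = self.n_clusters
        maps = self._kpp_seed(Xn, k, rng)
        labels = np.full(Xn.shape[0], -1)
        gev = -np.inf
        for _ in range(self.max_iter):
            r = Xn @ maps.T
            r2 = r**2
            new_labels = np.argmax(r2, axis=1)
            for j in range(k):
                if not np.any(new_labels == j):
                    worst = int(np.argmin(np.max(r2, axis=1)))
                    maps[j] = Xn[worst]
                    new_labels[worst] = j
            for j in range(k):
                maps[j] = self._principal_map(Xn[new_labels == j])
            r = Xn @ maps.T
            assigned_r2 = r[np.arange(len(Xn)), new_labels] ** 2
            new_gev = float(np.sum(gfp2 * assigned_r2) / np.sum(gfp2))
            if np.array_equal(new_labels, labels) or new_gev - gev < self.tol:
                labels, gev = new_labels, new_gev
                break
            labels, gev = new_labels, new_gev
        dispersion = float(np.sum(1.0 - r[np.arange(len(Xn)), labels] ** 2))
        return maps, labels, gev, dispersion

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be observations x channels")
        if X.shape[0] < self.n_clusters:
            raise ParameterError(
                f"{X.shape[0]} observations cannot support k={self.n_clusters}"
            )
        Xn = _normalize_rows(X)
        gfp2 = np.asarray(X - X.mean(axis=1, keepdims=True)).std(axis=1, ddof=0) ** 2
        if not np.any(gfp2 > 0):
            raise ParameterError("all observations are spatially constant")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            maps, labels, gev, w = self._fit_once(Xn, gfp2, rng)
            if best is None or gev > best[2]:
                best = (maps, labels, gev, w)
        self.maps_, self.labels_, self.gev_, self.dispersion_ = best
        return self

    def predict(self, X):
        """Backfit: class of the best-|correlation| map per observation."""
        Xn = _normalize_rows(np.asarray(X, dtype=float))
        return np.argmax((Xn @ self.maps_.T) ** 2, axis=1)

    def to_model(self, level="subject", channel_labels=None) -> MicrostateModel:
        return MicrostateModel(self.maps_.copy(), self.gev_, level, channel_labels)


def modified_kmeans(X, k: int, n_init: int = 20, seed=None,
                    level: str = "subject") -> MicrostateModel:
    """Functional wrapper around :class:`ModifiedKMeans`."""
    est = ModifiedKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return est.to_model(level=level)


@dataclasses.dataclass
class KLCurve:
    """Krzanowski–Lai criterion curve over a contiguous range of k."""

    k_values: np.ndarray
    W: np.ndarray       # within-cluster dispersion per k
    DIFF: np.ndarray    # dispersion increments per k
    KL: np.ndarray      # NaN at the last k (needs DIFF at k+1)
    k_opt: int


def select_k_kl(X, k_range=range(2, 9), n_init: int = 20, seed=None) -> KLCurve:
    """Choose the number of microstate classes by the Krzanowski–Lai criterion.

    ``W_k`` is the within-cluster dispersion under the 1 - r**2 metric;
    ``DIFF(k) = (k-1)**(2/p) W_{k-1} - k**(2/p) W_k`` with p = number of
    channels, and ``KL(k) = |DIFF(k)| / |DIFF(k+1)|``.  The optimum is the
    k maximizing KL: the last k at which adding a cluster still buys a
    large drop in dispersion.  ``W_1`` (needed by DIFF at the smallest
    tested k) is computed from the single principal topography, so the
    lower end of ``k_range`` is itself selectable; the upper end only
    provides the final denominator and is not.
    """
    ks = np.asarray(list(k_range))
    if len(ks) < 3:
        raise ParameterError("k_range needs at least 3 values (k-1, k, k+1)")
    if ks.min() < 2 or np.any(np.diff(ks) != 1):
        raise ParameterError("k_range must be contiguous with min >= 2")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    ks_fit = np.r_[ks[0] - 1, ks]  # include k-1 below the tested range
    W_fit = np.empty(len(ks_fit))
    for i, k in enumerate(ks_fit):
        est = ModifiedKMeans(
            n_clusters=int(k), n_init=(1 if k == 1 else n_init),
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        W_fit[i] = est.dispersion_

    DIFF = (ks_fit[:-1] ** (2.0 / p)) * W_fit[:-1] - (ks ** (2.0 / p)) * W_fit[1:]
    KL = np.full(len(ks), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        KL[:-1] = np.abs(DIFF[:-1]) / np.abs(DIFF[1:])
    k_opt = int(ks[:-1][int(np.nanargmax(KL[:-1]))])
    return KLCurve(ks, W_fit[1:], DIFF, KL, k_opt)


def fit_cohort(subject_models, k=None, n_init: int = 20, seed=None) -> MicrostateModel:
    """Cohort-level maps: re-cluster the pooled subject maps.

    Each subject contributes its k maps as observations; one further
    modified k-means pass over the pool yields maps comparable across the
    whole cohort.
    """
    if not subject_models:
        raise ParameterError("need at least one subject model")
    n_ch = {m.n_channels for m in subject_models}
    if len(n_ch) != 1:
        raise MetadataError(f"heterogeneous channel counts: {sorted(n_ch)}")
    if k is None:
        k = subject_models[0].k
    if any(m.k != k for m in subject_models):
        raise ParameterError("all subject models must have k maps")
    pool = np.vstack([m.maps for m in subject_models])
    model = modified_kmeans(pool, k, n_init=n_init, seed=seed, level="cohort")
    model.channel_labels = subject_models[0].channel_labels
    return model


def align_maps(model_a, model_b):
    """Optimally match model_b's maps to model_a's, up to sign.

    Returns ``(permutation, signs, corr)`` where ``permutation[i]`` is the
    index of the map in ``model_b`` paired with map i of ``model_a``,
    ``signs[i]`` makes the pair correlate positively, and ``corr`` is the
    full k x k spatial-correlation table (kept for visual inspection).
    The assignment maximizes the summed |correlation| over all one-to-one
    pairings.
    """
    A = _normalize_rows(model_a.maps if hasattr(model_a, "maps") else model_a)
    B = _normalize_rows(model_b.maps if hasattr(model_b, "maps") else model_b)
    if A.shape != B.shape:
        raise ParameterError("models must share k and channel count")
    corr = A @ B.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    signs = np.sign(corr[np.arange(A.shape[0]), perm])
    signs[signs == 0] = 1
    return perm, signs.astype(int), corr


def backfit(rec: EEGRecording, model: MicrostateModel,
            min_duration_ms: float = 0.0) -> LabelSequence:
    """Label every sample with its best-correlated microstate class.

    Assignment is by maximal squared spatial correlation (ties break to
    the lowest class index).  If ``min_duration_ms`` > 0, runs shorter
    than that are iteratively relabelled to whichever neighbouring class
    correlates better over the run, shortest runs first, until none
    remain — a simple temporal smoothing, off by default.
    """
    if model.channel_labels is not None and list(rec.labels) != list(model.channel_labels):
        raise MetadataError("recording channels do not match the model's")
    if rec.n_channels != model.n_channels:
        raise MetadataError("channel count mismatch between recording and model")
    Xn = _normalize_rows(rec.data.T)
    maps_n = _normalize_rows(model.maps)
    r2 = (Xn @ maps_n.T) ** 2
    labels = np.argmax(r2, axis=1)

    min_samples = int(round(min_duration_ms * rec.fs / 1000.0))
    if min_samples > 1:
        while True:
            runs = runs_of(labels)
            if len(runs) <= 1:
                break
            short = [r for r in runs if r[1] < min_samples]
            if not short:
                break
            start, length, _ = min(short, key=lambda r: r[1])
            i = next(idx for idx, r in enumerate(runs) if r[0] == start)
            cands = []
            if i > 0:
                cands.append(runs[i - 1][2])
            if i < len(runs) - 1:
                cands.append(runs[i + 1][2])
            seg = slice(start, start + length)
            best = max(cands, key=lambda c: r2[seg, c].mean())
            labels[seg] = best
    return LabelSequence(labels, rec.fs, n_classes=model.k)


# -- canonical class naming ------------------------------------------------

def idealized_templates(channel_labels) -> np.ndarray:
    """Synthetic idealized class A–D topographies for naming cohort maps.

    These are *geometric idealizations* built from standard 10-20 montage
    positions — not empirical group templates: A and B are the two mirror
    diagonal gradients, C the anterior–posterior gradient, and D the
    fronto-central focal pattern.  They capture the qualitative geometry
    of the four canonical resting-state classes well enough to assign
    stable names; the full correlation table should still be inspected.
    """
    import mne

    montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    lookup = {name.lower(): xyz for name, xyz in pos.items()}
    missing = [l for l in channel_labels if l.lower() not in lookup]
    if missing:
        raise MetadataError(f"channels without 10-20 positions: {missing}")
    xy = np.array([lookup[l.lower()][:2] for l in channel_labels])
    x, y = xy[:, 0], xy[:, 1]
    r2 = x**2 + y**2
    patterns = np.array([
        x + y,                 # A: left-posterior to right-anterior diagonal
        -x + y,                # B: mirrored diagonal
        y,                     # C: anterior-posterior gradient
        r2.max() - r2,         # D: fronto-central focal maximum
    ])
    return _normalize_rows(patterns)


def assign_canonical_names(model: MicrostateModel) -> list:
    """Name a 4-class model's maps A–D by alignment to idealized templates."""
    if model.k != 4:
        raise ParameterError("canonical A-D naming requires k = 4")
    if model.channel_labels is None:
        raise MetadataError("model lacks channel labels")
    templates = idealized_templates(model.channel_labels)
    perm, _, _ = align_maps(templates, model)
    names = [""] * model.k
    for i, letter in enumerate("ABCD"):
        names[perm[i]] = letter
    model.names = names
    return names


# -- serialization ---------------------------------------------------------

def save_model(model: MicrostateModel, path, config_hash: str | None = None) -> None:
    payload = {
        "k": model.k,
        "gev": model.gev,
        "level": model.level,
        "maps": model.maps.tolist(),
        "channel_labels": model.channel_labels,
        "names": model.names,
        "config_hash": config_hash,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> MicrostateModel:
    payload = json.loads(Path(path).read_text())
    return MicrostateModel(
        np.asarray(payload["maps"], dtype=float), float(payload["gev"]),
        payload.get("level", "subject"), payload.get("channel_labels"),
        payload.get("names"),
    )


def write_labels(seq: LabelSequence, path) -> None:
    """Label sequence as a single-column CSV; the header carries fs."""
    with open(path, "w") as fh:
        fh.write(f"label_fs_{seq.fs:g}\n")
        for v in seq.labels:
            fh.write(f"{int(v)}\n")


def read_labels(path) -> LabelSequence:
    from .recording import FormatError

    lines = Path(path).read_text().strip().splitlines()
    header = lines[0]
    if not header.startswith("label_fs_"):
        raise FormatError(f"{path}: missing label_fs_<fs> header")
    fs = float(header.removeprefix("label_fs_"))
    labels = np.array([int(v) for v in lines[1:]], dtype=np.int64)
    return LabelSequence(labels, fs)
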