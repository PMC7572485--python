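"""Microstate sequence statistics and group-comparison tests.

Per-recording statistics are the classical microstate set: mean duration
per class, coverage, and the Markovian syntax transition matrix.  Group
comparisons use a two-way (group x class) ANOVA with Type II sums of
squares, Mann–Whitney U tests reported with the normal-approximation
z-score as an effect size, and a permutation TANOVA for topographic
differences.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import LabelSequence, _normalize_rows, runs_of
from .recording import ParameterError


class DegenerateSequenceError(ValueError):
    """The label sequence has no transitions to analyse."""


@dataclasses.dataclass
class SequenceStats:
    """Duration, coverage and syntax statistics of one label sequence.

    ``mean_duration_ms[c]`` is NaN when class c has no (interior) run;
    such classes are listed in ``missing_duration_classes``.  The
    transition matrix has a zero diagonal and its entries sum to one.
    """

    n_classes: int
    coverage: np.ndarray
    mean_duration_ms: np.ndarray
    grand_mean_duration_ms: float
    transition_matrix: np.ndarray
    n_transitions: int
    missing_duration_classes: list


@dataclasses.dataclass
class TestResult:
    """A scalar test statistic with its p-value.

    ``statistic`` is U for Mann–Whitney (with ``z`` its normal
    approximation), F for ANOVA terms, and the topographic dissimilarity
    for TANOVA.  ``effect_direction`` is the sign of the first sample's
    shift relative to the second where that is meaningful.
    """

    statistic: float
    p: float
    z: float | None = None
    effect_direction: int = 0
    name: str = ""


def sequence_stats(seq, n_classes: int | None = None,
                   exclude_truncated: bool = True) -> SequenceStats:
    """Mean duration, coverage, and the normalized transition matrix.

    Durations are taken over maximal constant runs; runs touching either
    epoch boundary are censored (their true dwell is unknown) and excluded
    from duration means unless ``exclude_truncated=False``.  Coverage
    always uses all samples.  Transition counts are taken at label-change
    points and normalized by the total number of transitions.
    """
    if isinstance(seq, LabelSequence):
        labels, fs = seq.labels, seq.fs
        k = n_classes or seq.n_classes
    else:
        labels = np.asarray(seq, dtype=np.int64)
        fs = 1000.0  # samples are then milliseconds
        k = n_classes or (int(labels.max()) + 1 if len(labels) else 0)
    if len(labels) == 0:
        raise ParameterError("empty label sequence")
    runs = runs_of(labels)
    if len(runs) < 2:
        raise DegenerateSequenceError(
            "single-run sequence: durations and transitions are undefined"
        )

    coverage = np.bincount(labels, minlength=k).astype(float) / len(labels)

    dur_runs = runs[1:-1] if exclude_truncated else runs
    mean_duration_ms = np.full(k, np.nan)
    per_class: dict = {}
    for _, length, cls in dur_runs:
        per_class.setdefault(cls, []).append(length)
    for cls, lengths in per_class.items():
        mean_duration_ms[cls] = np.mean(lengths) / fs * 1000.0
    all_lengths = [length for _, length, _ in dur_runs]
    grand = float(np.mean(all_lengths) / fs * 1000.0) if all_lengths else float("nan")
    missing = [c for c in range(k) if np.isnan(mean_duration_ms[c])]

    trans = np.zeros((k, k))
    classes = [cls for _, _, cls in runs]
    for a, b in zip(classes[:-1], classes[1:]):
        trans[a, b] += 1
    n_trans = len(classes) - 1
    trans /= n_trans
    return SequenceStats(k, coverage, mean_duration_ms, grand, trans,
                         n_trans, missing)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def u_to_z(U: float, n1: int, n2: int, tie_term: float = 0.0) -> float:
    """Normal-approximation z for a Mann–Whitney U.

    Continuity-corrected toward the mean and tie-corrected in the
    variance; |U - mean| <= 0.5 clamps z to exactly zero.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    diff = U - mu
    if abs(diff) <= 0.5:
        return 0.0
    return (diff - 0.5 * np.sign(diff)) / np.sqrt(var)


def mann_whitney_z(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test with its z-score effect size.

    U counts pairs (x_i > y_j) with half-credit for ties (midranks); the
    two-sided p comes from the standard normal on the continuity- and
    tie-corrected z.  Fully degenerate input (all values identical) gives
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ParameterError("each sample needs at least one value")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    z = u_to_z(U, n1, n2, _tie_term(combined))
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    direction = int(np.sign(U - n1 * n2 / 2.0))
    return TestResult(U, p, z=float(z), effect_direction=direction,
                      name="mann_whitney")


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  factors=("group", "ms_class")) -> dict:
    """Two-way fixed-effects ANOVA with interaction, Type II SS.

    ``df`` is a tidy table with one row per observation.  Type II sums of
    squares keep main-effect tests well-defined for unbalanced designs
    (unequal group sizes), the usual situation in patient cohorts.
    Returns ``{factor_a: TestResult, factor_b: ..., "interaction": ...}``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    work = df[[value, fa, fb]].rename(
        columns={value: "y", fa: "fa", fb: "fb"}
    ).dropna()
    for col in ("fa", "fb"):
        if work[col].nunique() < 2:
            raise ParameterError(f"factor {col!r} needs at least 2 levels")
    cells = work.groupby(["fa", "fb"], observed=True).size()
    n_cells = work["fa"].nunique() * work["fb"].nunique()
    if len(cells) < n_cells:
        raise ParameterError(
            "empty factor cells; drop the unobserved level before the ANOVA"
        )
    keys = ((fa, "C(fa)"), (fb, "C(fb)"), ("interaction", "C(fa):C(fb)"))
    y = work["y"].to_numpy()
    if np.ptp(y) == 0:  # all values equal: nothing to explain, F = 0/0
        return {key: TestResult(0.0, 1.0, name=f"anova:{key}")
                for key, _ in keys}
    fit = smf.ols("y ~ C(fa) * C(fb)", data=work).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = {}
    for key, row_name in keys:
        F = table.loc[row_name, "F"]
        p = table.loc[row_name, "PR(>F)"]
        if not np.isfinite(F):
            F, p = 0.0, 1.0
        out[key] = TestResult(float(F), float(p), name=f"anova:{key}")
    return out


def tanova(maps_a, maps_b, n_perm: int = 999, seed=None) -> TestResult:
    """Permutation test for a topographic difference between two groups.

    Each subject contributes one unit-normalized map for the class under
    test.  Polarity is fixed once against the pooled consensus (the
    leading eigenvector of the pooled maps), which makes the statistic a
    deterministic function of group membership; the statistic is then
    ``1 - |r(mean_A, mean_B)|`` over the renormalized group mean maps.
    The null is built by permuting group membership; with the +1
    convention the attainable minimum p is ``1 / (n_perm + 1)`` (0.001 at
    the default 999 permutations).
    """
    A = _normalize_rows(np.asarray(maps_a, dtype=float))
    B = _normalize_rows(np.asarray(maps_b, dtype=float))
    na, nb = len(A), len(B)
    if na < 2 or nb < 2:
        raise ParameterError("each group needs at least 2 subject maps")
    pool = np.vstack([A, B])
    _, vecs = np.linalg.eigh(pool.T @ pool)
    signs = np.sign(pool @ vecs[:, -1])
    signs[signs == 0] = 1.0
    pool = signs[:, None] * pool

    def stat(idx_a, idx_b):
        ma = pool[idx_a].mean(axis=0)
        mb = pool[idx_b].mean(axis=0)
        denom = np.linalg.norm(ma) * np.linalg.norm(mb)
        if denom == 0:
            return 1.0
        return 1.0 - abs(float(ma @ mb)) / denom

    observed = stat(np.arange(na), np.arange(na, na + nb))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        if stat(perm[:na], perm[na:]) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(observed, float(p), name="tanova")
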