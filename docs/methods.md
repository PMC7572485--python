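# Methods

This note documents the models and procedures implemented in `mstates`,
the parameter choices that matter, and what the synthetic-data tests do
and do not establish about real EEG.

## Preprocessing

Recordings are stored in µV as channels × samples. The default chain is
the standard microstate one: zero-phase band-pass (forward–backward
4th-order Butterworth, 1–30 Hz), common-average reference, optional
polyphase resampling at an exact rational ratio (e.g. 512/1000 = 64/125,
so no cumulative drift), and retention of the first 20 s when the
recording is longer. Every step is configurable
(`PreprocessingConfig`); no artifact rejection or channel interpolation
is attempted — inputs are assumed clean (synthetic data is clean by
construction). Zero-phase filtering leaves boundary transients of a few
hundred milliseconds at each end of out-of-band components; pipelines
that epoch after filtering (as here, where the epoch is cut from the
filtered record) are only affected at the outermost samples.

The clinical conversion (`downsample_to_clinical`) restricts to the
19-electrode 10-20 montage (Fp1…O2), resamples (512 Hz by default), and
re-references to the average of the retained channels — emulating the
format of routine clinical EEG systems so that features computed on
research and clinical recordings live on comparable scales.

## Microstate model

Topographic maps are considered equivalent under sign inversion: the
generator of an EEG topography oscillates, so the field reverses
polarity within a state. All map computations therefore use the squared
spatial Pearson correlation.

**Clustering.** Observations are the topographies at GFP peaks (the
moments of highest topographic signal-to-noise; spatial standard
deviation is the GFP). `ModifiedKMeans` assigns each observation to the
map maximizing `r²` and updates each map as the first principal
eigenvector of its members' outer-product sum — the direction that
maximizes polarity-invariant explained variance. Seeding is k-means++
adapted to `d = 1 − r²`; 20 restarts are run and the restart with the
highest global explained variance (GEV) wins, where
`GEV = Σ_t (gfp_t · r_t)² / Σ_t gfp_t²` over assigned maps. Iteration
stops at a label fixpoint or when GEV improves by less than 1e-7. Empty
clusters are reseeded from the worst-fit observation. With a fixed seed
the fit is bit-reproducible. Clustering all samples instead of GFP peaks
is a config switch.

**Class count.** The Krzanowski–Lai criterion operates on the
within-cluster dispersion `W_k = Σ (1 − r²)` (same metric as the
clustering objective): `DIFF(k) = (k−1)^(2/p) W_{k−1} − k^(2/p) W_k`
with `p` the channel count, and `KL(k) = |DIFF(k)| / |DIFF(k+1)|`; the
selected k maximizes KL. `W_1` is computed from the single principal
topography so the smallest tested k is itself selectable; the largest
tested k only supplies the final denominator. On synthetic four-map EEG
at SNR 5 the criterion selects k = 4 essentially always (the KL value at
the true k exceeds the others by orders of magnitude).

**Cohort maps, alignment, naming.** Cohort-level maps are obtained by
re-clustering the pooled subject maps (k maps per subject). Models are
aligned by solving the assignment problem maximizing summed |r|
(Hungarian algorithm) with signs chosen to make aligned pairs correlate
positively; the full correlation table is returned for visual
inspection. For k = 4, classes are named A–D by aligning to *idealized*
template topographies constructed geometrically from standard 10-20
electrode positions (two mirrored diagonal gradients, an
anterior–posterior gradient, and a fronto-central focal pattern). These
are synthetic idealizations, not empirical group templates; the naming
is a convenience and the correlation table should be checked.

**Backfitting.** Every sample is labeled with the class of maximal `r²`
(ties break to the lowest index, deterministically). Optional temporal
smoothing relabels runs shorter than `min_duration_ms` to the better
correlated neighbouring class, shortest runs first; it is off by
default, and the choice is recorded in the output config hash.

## Sequence statistics

Durations are means over maximal constant runs, converted to ms; runs
touching an epoch boundary are censored (their true dwell is unknown)
and excluded by default. Coverage uses all samples. Transition counts
are taken at label changes and normalized by the total transition count
(zero diagonal, entries summing to 1). A single-run sequence has no
transitions and raises rather than returning silent NaNs.

Group comparisons: two-way fixed-effects ANOVA (group × class) with
interaction and Type II sums of squares — Type II keeps main-effect
tests well-defined in the unbalanced designs typical of patient cohorts
(the choice matters only when cell sizes differ). Significant parametric
results are conventionally post-hoc checked with Mann–Whitney U tests;
`mann_whitney_z` reports midrank U, the tie-corrected
continuity-corrected normal z as an effect size, and the two-sided
normal p. Exhaustive comparison with exact enumeration shows the
approximation stays within 0.02 of the exact p for groups of ≥ 5; below
that it can deviate by up to ~0.04 and exact tests should be preferred.

**TANOVA.** Each subject contributes one unit-norm map per class.
Polarity is fixed once against the pooled consensus (leading eigenvector
of the pooled maps), making the statistic a deterministic function of
group membership; the statistic is `1 − |r|` between the renormalized
group mean maps, and the null is built by permuting group membership.
With 999 permutations and the +1 convention the attainable minimum p is
exactly 0.001. Per-group polarity re-alignment was considered and
rejected: under permutation it lets imbalanced mixed groups cancel their
minority component and produce spuriously extreme statistics, destroying
the floor behaviour on strongly separated groups.

## Complexity measures

**LZ76.** The parser implements the 1976 exhaustive history: the current
word is extended while it occurs in the extended prior history
(self-overlapping reproduction allowed); when extension fails, the word
— including the failing symbol — closes; the terminal word counts even
if reproducible. Conventions: empty → 0, single symbol → 1, `AAAA` → 2
(`A·AAA`), `ABAB…` → 3 (`A·B·ABAB…`). Alternative conventions differ by
±1; this one is pinned by an exhaustive brute-force oracle over all
binary strings up to length 12.

**Microstate LZC (C).** By default C is the raw LZ76 word count of the
run-collapsed transition sequence — collapsing makes C independent of
sampling rate and dwell durations, isolating the *pattern* of
transitions. Both the collapse and the optional `log_k(n)/n`
normalization (which maps random sequences near 1) are flags recorded in
every output; features computed under different flags are never mixed
(config-hash check). A single-class sequence returns the degenerate
minimum C = 1.

**Comparison measures.** Ω-complexity is `exp(−Σ λ'_i ln λ'_i)` over the
normalized eigenvalues of the channel covariance — an effective count of
independent spatial components (1 for rank-one data, ≈ N−1 for N
uncorrelated average-referenced channels). Time-series LZC binarizes
each channel at its median (scale-free), applies LZ76, normalizes by
`n / log2(n)`, and averages over channels — the classical univariate
EEG-complexity recipe.

## Spectral feature

θRP is computed from Welch PSDs (2 s Hamming segments, 50% overlap) as
the trapezoidal band integral over 4–8 Hz divided by the 1–30 Hz
integral, averaged over channels. Band edges are config, not constants,
and are echoed in outputs. Integration interpolates the PSD at the exact
band edges so that relative powers over a partition of the total band
sum to one. θRP is invariant to global amplitude scaling.

## Classifier

`MicrostateSVC` standardizes (θRP, C) per feature and fits an SVM; the
default kernel is RBF with C = 1 and the median-heuristic bandwidth
(`gamma = 1/(2·median²)` of pairwise distances on the standardized
training features), a parameter-free default that adapts to the feature
scale; a linear kernel is available by config. Evaluation is stratified
k-fold (default 10, seeded) with the scaler and bandwidth refit per
training fold and out-of-fold predictions pooled into one confusion
matrix. Reported percentages are rounded half-away-from-zero to one
decimal; unrounded values are retained. Applying a model to features
from another cohort requires matching feature-config hashes; converting
between channel formats therefore means recomputing features and
retraining, never silently reusing the old decision surface. When an
AD-vs-control model predicts MCI outcomes, predictions are mapped
(AD→converter, control→stable) and the converter class is scored as
positive.

## Synthetic data

The generator emulates the target study conditions: 64-channel (or any
montage) eyes-open rest, 20 s at 250 Hz by default, four unit-norm
zero-mean topographies (orthonormalized random directions smoothed along
the electrode axis, pairwise |r| < 0.5), gamma-distributed dwell times
(mean 60 ms, shape 2 — a semi-Markov process, deliberately
non-Markovian, so the complexity measure's target regime is exercised),
uniform transitions unless specified, a 10 Hz carrier with phase
re-randomized at each switch (alpha-dominant rest), and i.i.d. Gaussian
sensor noise scaled so RMS(signal)/RMS(noise) equals the requested SNR
exactly (default 5). Defaults were chosen once as the study conditions
and are not tuned.

What the generator does *not* emulate: 1/f background spectra, spatially
correlated noise, artifacts, volume-conduction forward physics, and
within-state topographic drift. Passing tests therefore establish
algorithmic correctness and parameter recovery under the stated model,
not clinical performance: at SNR 5 the carrier's amplitude zero-crossings
produce brief noise-dominated samples that fragment backfit runs, which
is why recovered mean durations (≈40 ms) sit below the generating dwell
mean (60 ms) while label accuracy away from switches exceeds 90% —
real-data duration estimates share this smoothing-dependence.

Feature cohorts for classifier tests are plain Gaussians per group in
(θRP, C) space, with the disease-like group given higher θRP and lower C
(the direction of the effect the measures are designed to capture).

## Problem sizes and determinism

Tests and the acceptance script run the full study geometry per subject
(64 × 5000 samples) but keep cohort sizes small (6–20 subjects) and use
10 simulated subjects for the class-count experiment; these sizes give
stable medians while keeping a full run in tens of seconds. All
randomness flows through explicit integer seeds (numpy `default_rng`);
repeated runs are byte-identical. Permutation counts: 999 for reported
TANOVA p-values (floor 0.001), 199 inside the null-calibration property
test.

## Known limitations

- No artifact handling; real clinical EEG needs upstream cleaning.
- The A–D naming templates are geometric idealizations; on unusual
  montages or atypical cohort maps the assignment should be inspected.
- The EDF writer covers plain continuous 16-bit EDF with 1 s records and
  integer sampling rates — sufficient for exporting synthetic data, not
  a general-purpose EDF+ implementation.
- Exact Mann–Whitney p-values are approximated via the normal z; for
  groups smaller than 5 use exact enumeration.
- Source localization of map differences is out of scope (requires a
  head model / lead field).
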