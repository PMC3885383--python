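# Methods

This note records the models, conventions, and numerical choices behind
`pibcast`, and what the synthetic-data tests do and do not establish.

## Conventions

Time is in seconds from record start; all intervals are half-open
`[start, end)`. Signals are channels × samples in µV with a single
per-sample validity mask shared across channels (telemetry dropouts affect
the whole montage). Report display rounds durations to whole days, summary
means/stds to 1 decimal, sensitivities to 3 decimals, p-values to 4, and
FP/day to 3.

## Power-in-band features

Blocks are 60 s (block length × sampling rate must be an integer sample
count); a block is valid only if *every* sample in it is valid; a trailing
partial block is dropped. The record is average-referenced (instantaneous
across-channel mean subtracted) before blocking.

The spectral estimate is the plain periodogram of the mean-removed block:
no taper, no overlap. Normalization is chosen so that the sum of all
positive-frequency bin powers equals the biased sample variance of the
block (Parseval); PIB values are therefore in µV². Each bin at frequency f
belongs to the band whose half-open `[lo, hi)` interval contains it, so the
shared edges 4, 8, 12, 30 and 70 Hz belong to the upper band; the DC bin
and bins at or above 180 Hz are discarded. Consequently the six band powers
of a channel sum exactly to its 0.1–180 Hz spectral power, and band
assignment over [0.1, 180) Hz is exhaustive and exclusive. Bands reaching
above Nyquist are clipped with a logged warning.

For a 60 s block the bin spacing is 1/60 Hz, so "0.1 Hz" excludes the first
five non-DC bins; sub-0.1 Hz content never enters the features.

## Labeling and cross-validation

A block is pre-ictal iff its start lies in `[onset − 90 min, onset)` for
any seizure; windows of clustered seizures union. Blocks overlapping an
ictal span `[onset, offset)` are excluded from training and testing by
default: labeling them inter-ictal (the literal convention) would teach the
classifier seizure rather than pre-seizure signatures. The
`ictal_as_interictal` flag restores the literal behavior. Post-ictal blocks
get no special label. A pre-ictal window truncated by a data gap keeps its
surviving valid blocks.

Lead seizures are those with no other onset in the preceding 4 h (the
record's first seizure is lead by construction).

Folds are contiguous runs of *valid* blocks balanced on valid-block count
(sizes differ by ≤ 1). Balancing on block count rather than wall-clock time
equalizes the training data available per fold when gaps are uneven; the
alternative (equal-duration sub-records) would make folds with heavy
dropout much smaller.

## Classifier

Features enter as `log10(PIB + ε)` (ε = smallest positive normal double, a
guard against empty bands) standardized per feature with training-fold
statistics, making risks invariant to affine rescaling of raw power.
The fit is L2-penalized logistic regression (scikit-learn lbfgs,
`C = 1/ridge`, default ridge 1e-4 — small enough to leave well-conditioned
problems essentially unpenalized, large enough to keep separable noise
features finite). Forward selection is greedy on mean AUC over a nested
*contiguous* inner split of the training rows (5 inner folds at full scale);
the criterion matches the ranking use of the risks and respects temporal
structure. Ties break to the lowest column index, making the whole
procedure deterministic. Selection, scaling and fitting are redone per
outer fold and never see test-fold rows; a training split lacking pre-ictal
blocks is reported and skipped rather than fit.

## Warnings and time-in-warning control

Each supra-threshold block opens a 90-min warning from its block start;
overlapping or abutting warnings merge; warnings clip at the record end.
Warnings run on wall-clock time and may span data gaps — a deployed device
cannot retract a warning — and the TIW denominator is the full record span.

Threshold calibration exploits the fact that realized TIW is a
non-increasing step function of θ with steps at observed risk values:
bisection over the sorted unique risks (plus one candidate below the
minimum for the TIW → 1 limit) finds the value whose realized TIW is
closest to target, ties resolving to the larger threshold (less warning).
Constant risk series are degenerate: the threshold is set at/above the
constant (TIW 0) with a logged warning. "Approximately matches" has no
stated tolerance; the achieved |TIW − target| is reported instead of
enforced.

In the full pipeline each fold's threshold is calibrated on that fold's
*training* risks (the model applied to its own training blocks) and frozen
before touching test data. The calibration denominator is training time,
not record span, so the warning *rate* matches the target and the test fold
realizes approximately the target TIW. Residual deviation (typically a few
points at TIW 0.3) comes from the persistence nonlinearity: merged coverage
amplifies small differences between in-sample and out-of-fold trigger
rates.

Scoring: a seizure is a true positive iff some warning starts ≥ horizon
(5 min) before its onset and is still active at onset. A merged warning
containing no onset is one false positive; a seizure inside
`[start, start + horizon)` is a false negative but its warning is *not* a
false positive (the two rules are applied literally). The lead-only
analysis restricts the sensitivity denominator to lead seizures; FP counts
and TIW are unchanged, and a warning containing only non-lead onsets is
still not a false positive.

## Chance predictor and significance

The null warning generator draws onsets from a homogeneous Poisson process
at rate λ = −ln(1 − TIW)/τ (τ = persistence), each opening a τ-length
warning, merged and clipped exactly like candidate warnings; the Boolean
coverage model makes the expected merged coverage equal the matched TIW.
The closed-form per-seizure hit probability `1 − exp(−λ(τ − h))` (exactly
TIW at h = 0) ignores merging and is provided as a documented
approximation; the primary p-value is Monte Carlo: chance warning sets are
scored against the fixed observed seizure times (conditioning preserves
clustering under the null), one-sided, with the add-one estimator
`p = (1 + #{S_chance ≥ S_obs}) / (1 + n_mc)` so p is never 0. Because the
printed "adjusted" sensitivity has no unique definition, both
`S_obs − mean(S_chance)` and `(S_obs − mean)/(1 − mean)` are reported
alongside the raw value.

The matched design makes the p-value mildly conservative when the candidate
is itself a chance-like process: matching the null on the candidate's
*realized* TIW removes coverage-luck from the null but not from the
candidate. The calibration self-test therefore draws candidate and null
from the identical process (same target TIW), the exchangeable construction
under which p is uniform up to discreteness of the sensitivity.

## Synthetic data: what it emulates, what it does not

Seizure times follow a Poisson cluster (Neyman–Scott-like) process: lead
events at `lead_rate`/day, geometric cluster sizes (mean
`cluster_size_mean`), log-normal intra-cluster gaps (median 30 min, log-sd
0.5), fixed 60 s ictal duration. Expected totals are
`lead_rate · days · mean cluster size`, slightly reduced by end-of-record
truncation and collision dropping. With ~5 clusters of mean size 5.4 over
197 days the count distribution centers near 27 events, the regime of the
longest-observed cohort subject.

Feature-level synthesis draws iid Gaussian log10-PIB per block (per-band
baselines falling from 2.0 at δ to −0.2 at γ-high, log10-sd 0.3) and shifts
designated features by log10(gain) inside pre-ictal windows, optionally with
a linear ramp toward onset. Block-level invalid gaps hit an exact total
fraction with configurable mean run length. Raw synthesis builds each
channel in the frequency domain (1/f^α background plus Gaussian-bump
band-limited oscillations), scales targeted band amplitudes by √gain inside
pre-ictal windows, and refuses month-scale rendering (memory budget) in
favor of the feature-level path.

Not emulated: circadian rhythms, seizure morphology, spatial correlation
structure across channels, post-ictal suppression, and nonstationary
baselines. Passing the end-to-end tests therefore shows the *pipeline*
recovers a planted pre-ictal power shift at controlled chance levels — not
that real iEEG contains such a shift. The raw-signal and feature-level
generators are distinct models and are not parameter-matched; their shared,
tested contract is the configured pre-ictal power ratio as seen by the
feature extractor.

## Problem sizes and defaults

Full-scale defaults mirror the reference configuration (96 features, 10
selected, 10 folds, 5 inner folds, TIW grid 0.1–0.5, n_mc 1000). The
desk-scale study conditions used by the end-to-end tests and the acceptance
script are chosen once: 30-day feature-level subjects, 2 channels
(12 features, 3 selected), 0.2 clusters/day with mean size 3.3 (≈ 20
seizures), 10 outer / 3 inner folds, target TIW 0.3, n_mc 199, 20 seeds per
arm. A planted 4× α-power gain on one channel is recovered as
better-than-chance forecasting (p < 0.05) in ≥ 90% of seeds, while the null
(gain 1) keeps p ≥ 0.05 at its nominal rate. All randomness flows from one
master seed through named `numpy` SeedSequence substreams (simulation,
chance Monte Carlo), so identical seeds give bit-identical catalogs,
features, risks, and reports.

## Known limitations

* The EDF writer emits plain 16-bit EDF (1 s records, integer sampling
  rates); validity masks survive only in the container format, and EDF+
  annotations are honored on read only as `bad*` → invalid.
* Per-subject truncation of early post-implantation data is exposed as an
  optional analysis window, with no default truncation rule.
* The analytic chance sensitivity is exact only without merging; at high
  TIW it understates the Monte-Carlo value.
* Forward selection cost grows as O(p · k) logistic fits per fold; at the
  full 96-feature scale a months-long record is an hours-scale computation
  on one core.
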