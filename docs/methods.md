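# Methods

`eegpls` re-implements, as a tested library, a two-level analysis of
resting-state EEG correlates of antidepressant treatment response: group
differences between eventual responders and non-responders in functional
connectivity (weighted phase lag index, WPLI) and signal complexity
(multiscale entropy, MSE) across three assessment sessions, followed by
single-participant analyses that ask how well each individual expresses the
group-level pattern.  Because the package is exercised on synthetic data,
every stage is paired with a generator that injects known effects, so
recovery can be verified quantitatively.

## Signal model of the synthetic cohort

Each recording is a set of 2-s epochs (500 Hz, 1000 samples) per
participant, session (baseline, week 1, week 12) and state (eyes-closed,
eyes-open).  A channel is a sum of three components:

* independent 1/f-amplitude ("pink") noise, unit SD, weight `w_pink`;
* independent white noise, weight `1 - w_pink`;
* zero or more *shared sinusoids*: an oscillator at frequency `f` placed on
  a set of channels with channel-specific phase offsets (default spacing
  pi/4) and a common random phase per epoch.

This shared-oscillator-plus-noise model was chosen over autoregressive
alternatives because it controls exactly what WPLI measures — the
consistency of a *nonzero* phase lag across observations — in closed form:
the oscillator amplitude sets the per-bin signal-to-noise ratio and hence
the expected WPLI, and the offsets avoid 0 and pi so the coupling is
visible to a lag-based estimator.  An optional common additive source with
*zero* lag on all channels serves as a volume-conduction stressor: WPLI
must ignore it.

Effects are injected per (group, session) cell.  Connectivity effects set
the oscillator amplitude; complexity effects shift `w_pink`, because a
larger 1/f fraction raises coarse-scale and lowers fine-scale sample
entropy.  A configurable *deviant fraction* of participants receives the
opposite group's profiles, emulating the individual deviation from group
patterns the single-participant analyses are designed to expose; the
generator's ground-truth record stores each participant's assignment.

Ages are drawn per group from truncated normals (responders 35.1 ± 10.5,
non-responders 44.8 ± 11.5, truncated to [18, 65] years) so that age is
correlated with group and the confound-regression stage is genuinely
exercised.  Default cohort structure: 25 responders + 18 non-responders,
63–113 artifact-free epochs per recording (drawn uniformly), 28 channels.

What the generator does *not* emulate: volume-conducted scalp topographies
from dipole sources, artifacts (blinks, muscle), non-stationarity within
epochs, or realistic cross-frequency structure.  Passing recovery tests
therefore demonstrates that the estimators and inference machinery behave
correctly under controlled conditions, not that the pipeline's findings on
real EEG are substantively correct.

## Connectivity: weighted phase lag index

For observations `k` of the cross-spectrum `X_k = c_i conj(c_j)` between
two channels,

    WPLI = | sum_k Im(X_k) | / sum_k |Im(X_k)| .

Weighting by the magnitude of the imaginary part gives angle differences
near ±pi/2 the most influence and makes the estimator insensitive to
zero-lag (volume-conducted) coupling; values lie in [0, 1].  The
magnitude-weighted form (not the debiased squared variant) is implemented.
A zero denominator — all observations purely real — yields 0 with a flag,
never NaN, so feature matrices stay complete.

Two observation routes:

* **Across-epoch (Fourier).**  Per epoch, tapered FFT coefficients on a
  0.5-Hz grid; bins up to 30 Hz use a single Hanning taper, bins from
  31 Hz a dpss multitaper with 2 Hz half-bandwidth (2TW − 1 = 7 tapers for
  2-s epochs), each taper contributing one observation.  The default grid
  is 1.0–50.0 Hz (99 bins): the 0.5 Hz bin is excluded because a single
  cycle per 2-s epoch cannot be estimated reliably.  The boundary bin at
  30.5 Hz belongs to the multitaper side; both the boundary and the grid
  are configurable.
* **Within-epoch (Morlet).**  Complex Morlet coefficients per time point,
  wavelet length rising linearly from 3 cycles at 4 Hz to 7 cycles at
  50 Hz (`c(f) = 3 + 4 (f − 4)/46`), Gaussian SD `sigma_t = c/(2 pi f)`,
  truncated at ±3 sigma.  Frequencies below 4 Hz are refused (three cycles
  of a sub-4-Hz wavelet exceed a 2-s epoch).  Time points within half the
  wavelet support of either edge are masked to avoid edge-artifact phase
  estimates.  WPLI over within-epoch time points yields one matrix per
  epoch — the representation single-participant analyses need — plus the
  across-epoch average used for Morlet-route group analyses.

The within-epoch estimator has a higher null floor than the across-epoch
one because neighbouring time points are strongly correlated (the effective
number of independent phase observations is set by the wavelet bandwidth,
not the sample count).  Null WPLI is positively biased at roughly
`sqrt(2 / (pi K))` for `K` independent observations; tests and acceptance
checks size their observation counts so that systematic effects are
resolvable against this floor.

## Complexity: multiscale entropy

Scale `tau` coarse-grains a series by averaging non-overlapping blocks of
`tau` samples (scale 1 is the raw series; scale 20 of a 1000-sample epoch
leaves 50 points, the minimum accepted).  Sample entropy with template
length `m = 2` and tolerance `r = 0.5 × SD` counts template pairs over
start points `i < j` in `[0, N − m)`: `B` pairs matching over `m` points
(Chebyshev distance ≤ r), `A` pairs additionally matching at point `m + 1`,
and returns `−ln(A/B)`; self-matches are excluded.  `r` is computed from
the *population* SD of each epoch's scale-1 series and held fixed across
scales (the convention of the physionet reference algorithm); this makes
the measure invariant to positive amplitude rescaling.  Undefined values
(`A = 0` or `B = 0`) are masked, excluded from epoch averaging and never
imputed.  Note that `−ln(A/B)` is not bounded by 1; the package implements
the standard definition.  The counting kernel is compiled with numba; the
test suite checks it for exact agreement against an independent brute-force
template counter.

## Feature assembly and age regression

Group matrices stack one row per participant × session (group-major),
columns the flattened element grid — frequency × pair (99 × 378 = 37 422
for the default across-epoch grid) or channel × timescale (28 × 20 = 560).
Individual matrices stack one row per epoch, grouped by session.

Age is regressed out of every column by one pooled ordinary-least-squares
fit across all rows before the group statistics.  Pooling both groups in a
single fit avoids re-introducing group differences through group-specific
intercepts; residuals are returned plus the column's grand mean so features
keep their original scale and interpretability.  Within-person (epoch-level)
analyses are untouched: a constant age cannot confound session contrasts.

## Mean-centered PLS-SVD

The group analysis averages the (age-corrected) features within each
group × session cell, subtracts each feature's unweighted grand mean of the
cell means, and decomposes the centered cell-mean matrix by SVD.  Removing
the grand mean across *all* cells (rather than within group) exposes group,
condition and interaction effects together, which is the variant that
matches an omnibus group × session analysis; within-group centering is a
one-line configuration change.  Each latent variable (LV) carries a
singular value, design saliences (the group/condition contrast expressed),
element loadings (the singular image), and the percentage of crossblock
covariance explained, `PCCE_i = 100 s_i² / Σ s_j²`.

* **Permutation test.**  Each of 500 permutations shuffles session labels
  within every participant *and* reassigns participants to groups with
  sizes preserved, then re-runs centering + SVD.  The p-value uses the
  add-one estimator `(1 + #{s_perm ≥ s_obs}) / (n_perm + 1)`: unbiased,
  never exactly zero.
* **Bootstrap.**  200 replicates resample participants with replacement
  within group; each replicate decomposition is aligned to the original by
  orthogonal Procrustes on the design saliences, which resolves the
  sign/order indeterminacy of the SVD.  The bootstrap ratio divides each
  original loading by the bootstrap standard error of the aligned replicate
  loadings; |BSR| > 2 marks ~95%-stable and |BSR| ≥ 3.1 ~99%-stable
  elements.  Condition-mean brain scores (row features · loadings) get 95%
  CIs from the 2.5/97.5 percentiles of replicate condition means.

Follow-up per-group analyses are gated on the omnibus LV1 being significant
*and* expressing a group × session interaction.  The gate decomposes the
LV1 saliences (reshaped group × session) into grand mean, main effects and
interaction; follow-ups run when the interaction component carries more
than 10% of the salience norm.  A fixed-threshold share was chosen over a
formal interaction test because the saliences are unit-norm weights, not
data with sampling error of their own; 10% is well below the share any
visible crossover pattern produces (≥ 35% in the replica) and above
numerical noise.  Follow-ups are judged at a Bonferroni-corrected
alpha = .025 (two tests per omnibus analysis).

## Non-rotated (contrast) PLS for individuals

For single-participant analyses the design salience is fixed a priori as a
zero-sum session contrast: `(0, 1, −1)` for connectivity (change from
week 1 to week 12, direction left to the data), and `(1, 0, −1)` (linear,
the responder pattern) plus `(1, 1, −2)` (late-only change, the
non-responder pattern) for complexity.  Condition means of the epoch-level
features are grand-mean centered; the loading vector is the unit-contrast-
weighted sum of centered means and the singular value its norm.  With a
positive weight on week 1, a feature that *decreases* from week 1 to
week 12 loads positively.  Permutations shuffle the epoch → session
assignment uniformly (epochs exchangeable under the null); bootstrap
replicates resample epochs within session.  No multiple-comparison
correction is applied at this level — the analyses aim to *find* the group
pattern in individuals — but each record also notes whether it survives a
stricter alpha = .001.

## Group-to-individual similarity

The group pattern for each outcome group is the singular image of that
group's follow-up LV, restricted to its |BSR| > 2 elements (at least 10
required), taken from the analysis living on the same feature grid as the
individual analyses (the Morlet-averaged connectivity analysis; the
epoch-averaged MSE analysis).  Because an SVD LV's sign is arbitrary, the
group LV is first sign-aligned to the predefined contrast; without this the
correlation's sign would be a convention artifact.

An individual matches the contrast when their non-rotated analysis is
significant (p < .05).  For matching participants, Pearson r between the
group pattern's stable loadings and the individual's loadings at the same
elements is categorized: r ≥ .4 moderate–strong (inclusive boundary),
.1 < r < .4 weak positive, −.1 ≤ r ≤ .1 negligible, r < −.1 negative.
Non-significant individuals are reported as showing no correlation with the
group pattern.  The correlation uses the *group* pattern's stability mask
only; the individual's own BSR map plays no role in the correlation path.

The visual-rating procedure of the original analysis is replaced by a
deterministic rule-based analogue.  Each rule window selects elements
(e.g. alpha 8–14 Hz, beta 18–30 Hz; coarse timescales 10–20), a required
loading sign, and optionally a timing constraint on the LV's brain-score
condition profile ("early change" vs "no early change", judged by the
ratio of the baseline→week-1 change to the week-1→week-12 change, cutoff
0.5).  A window fires when at least 5% of its elements are stable with the
required sign *and* that sign is the predominant direction among the
window's stable elements.  The majority condition mirrors what a human
rater does — judge the dominant direction of change in a band — and is
what makes the flags robust: stable elements of the opposite sign arise
both by chance and through systematic off-frequency effects of narrowband
signals on the within-epoch estimator.  The four rating categories
(own-pattern-only, both, opposite-only, neither) follow from the
fits-responder / fits-non-responder flags and the participant's group.

## The scaled study replica

The end-to-end recovery checks run a reduced replica of the full design:
12 + 9 participants, 10 channels (45 pairs), 20–30 epochs per recording,
Fourier grid 2–30 Hz (0.5-Hz bins), Morlet grid 4–30 Hz (1-Hz steps),
deviant fraction 0.1, with the study-motivated effects: responders lose
10 Hz coupling and gain 22 Hz coupling from week 1 to week 12
(non-responders the opposite), responders show an early widespread
coarse-scale entropy decrease (linear profile) while non-responders show a
late decrease confined to three posterior channels.  Oscillator amplitudes
(0.4 vs 0 relative to unit noise) were chosen from the calibration curve of
expected WPLI against per-bin SNR so that "present" coupling sits near the
top of the WPLI range and "absent" at the noise floor — i.e. a clearly
detectable effect, as in the original findings.  These problem sizes keep
the whole replica under a few minutes of compute while leaving every
inferential stage (permutation, bootstrap, follow-up gating, similarity)
statistically well-powered.

Ground truth for stability checks marks the coupled pairs at bins within
0.5 Hz of each oscillator as *injected* and excludes a 2-Hz guard band
around each oscillator on its pairs from the *null* set, because spectral
leakage makes that neighbourhood neither cleanly signal nor cleanly noise.

A note on inverted-pattern checks: for connectivity, the opposite group's
profile is an exact sign inversion of the injected change, so deviant
participants must categorize negative.  For complexity — as in the original
findings — both groups' profiles share the *direction* of coarse-scale
change and differ in timing and extent, so opposite-profile deviants
correlate positively (weaker) with the group pattern; the negative-category
recovery check is therefore a connectivity-path property.

## Numerical choices and degenerate inputs

* Cross-spectra are kept in double precision; WPLI amplitude invariance
  holds to 1e−10.
* SVD LVs fix their sign by making the largest-magnitude design salience
  positive; pattern extraction re-aligns to the predefined contrast.
* Bootstrap ratios with zero bootstrap SE are set to 0 when the loading is
  zero and capped at ±1e6 otherwise.
* Degenerate similarity inputs (zero variance over the stable mask, fewer
  than 10 stable elements, missing group pattern) raise or mark the record
  "not assessable" explicitly; nothing is silently defaulted.
* All randomness flows from `numpy.random.SeedSequence` spawns of a single
  seed; identical configurations produce byte-identical result JSON.

## Known limitations

* The generator's oscillators are strictly sinusoidal; estimator behaviour
  under broadband or bursty coupling is not covered by the recovery tests.
* The within-epoch WPLI's dependence on wavelet bandwidth means its null
  floor varies with frequency; group inference absorbs this (the floor is
  session-invariant), but absolute within-epoch WPLI values should not be
  compared across frequencies.
* The rule-based rating analogue is deterministic and therefore cannot
  reproduce inter-rater variability; it represents one defensible reading
  of the published rating criteria.
* EDF export is not provided; recordings are serialized to HDF5 only.
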