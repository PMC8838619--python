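# Methods

## Generative model

Each synthetic record is a concatenation of beats. Beat *k* has period
T_k = (60 / HR)·(1 + ε_k) with ε_k ~ N(0, period_cv/100), and over its own
period the pressure is

    x(t) = dc + Σ_{n=1..10} A_{k,n} · cos(2π n t / T_k + φ_{k,n} · π/180)

with A_{k,n} = A_n·(1 + δ_{k,n}), δ ~ N(0, amp_cv_n/100) (clipped at zero)
and φ_{k,n} = φ_n + N(0, phase_sd_n) degrees. White Gaussian noise
(`noise_sd`) and a slow sinusoidal baseline drift (`drift_amplitude`,
0.1 Hz) are added afterwards. Because every beat is a *finite* cosine
series, the spectral extractor's model is exactly realizable and each
configured quantity has an exact generative counterpart; a ground-truth
table of all drawn A, φ, T accompanies every record.

The template amplitudes come from the first ten Fourier harmonics of a
canonical beat shape — an asymmetric Gaussian with a sharp systolic
upstroke and gradual diastolic decay — whose harmonic amplitudes decline
monotonically (≈ 1 : 0.85 : 0.65 : … : 0.007), as arterial pulse spectra
do. Template phases are shifted so the pulse foot sits exactly at t = 0
(see *Beat-onset fiducial* below), making the generator's beat origin and
the segmenter's phase reference the same point.

### Cohort structure and severity coupling

A cohort draws, per subject: a template perturbed by a multiplicative
lognormal factor exp(N(0, σ)) per harmonic (σ = 0.1 default — the simplest
heavy-tail-free between-subject heterogeneity model), a small additive
phase offset (SD 2°), an integer MMSE from the group's (mean, sd) clipped
to [0, 30], and a heart rate from N(group HR, 6 bpm). A latent severity
s = (30 − MMSE)/30 then multiplies harmonics 4–10 by (1 + 0.6·s) and all
jitter levels by (1 + s). This makes generated MMSE anti-correlated with
higher-harmonic content and beat-to-beat variability *within and across*
groups, which is the structure the probability-vs-MMSE regression relies
on. Per-subject random streams are keyed by (seed, group index, subject
index) through `numpy.random.SeedSequence`, so one subject's record never
changes when other groups' sizes do.

### Default study configuration

Five groups, 38/38/20/19/8 subjects (AD, Control, community Sites A and B,
Young), 180 s records at 500 Hz. Group MMSE means/SDs (AD 12.16 ± 5.52,
Site A 21.84 ± 5.19, Site B 23.95 ± 4.39) and mean heart rates follow the
published subject characteristics of the study design this pipeline
targets; Control (28 ± 1.5) and Young (29 ± 1) MMSE values are nominal
healthy scores. Waveform-level defaults are the package's own choices,
ordered to reproduce the qualitative contrasts the analysis assumes:
high-harmonic boost 1.25 / 1.00 / 1.18 / 1.08 / 0.95 and amplitude-jitter
CV 7 / 4 / 6 / 5 / 3.5 % for AD / Control / SiteA / SiteB / Young, phase
jitter 5 / 2.5 / 4 / 3.2 / 1.5°, period CV 3–5 %, noise SD 0.005 (0.5 % of
the fundamental amplitude), drift 0.05. Harmonic 1 keeps a 1 % amplitude
CV: it is the amplitude-proportion reference, and jitter on the reference
enters every Cₙ ratio.

These defaults produce *cleaner* group separation than clinical data — the
default AD/Control cohort is classified with AUC ≈ 1.0, versus ≈ 0.70
reported for real recordings. No attempt was made to calibrate synthetic
effect sizes to clinical discrimination levels, since the clinical
recordings are unavailable; accordingly, passing tests demonstrate the
pipeline's correctness (index arithmetic, parameter recovery, calibration,
fold handling), not clinical-grade effect sizes. Other realism limits: no
physiologically mechanistic hemodynamics (no Windkessel or wave-reflection
model), no motion artifacts beyond white noise and drift, no explicit age
effect, and no respiratory modulation beyond the single drift sinusoid.

## Beat-onset fiducial

Onsets are pulse feet. Candidate systolic upstrokes are maxima of the
first derivative of a 0.5–15 Hz band-passed copy of the signal, found in
two passes: first with a threshold of half the 99th percentile of the
positive derivative and a 0.25 s minimum spacing, then re-found with a
threshold of 0.35× the median upstroke height and a refractory period of
0.4× the median inter-upstroke interval. Each foot is then localized on
the *raw* signal by the intersecting-tangent construction: the tangent at
the steepest upstroke sample is intersected with the horizontal line
through the minimum of the preceding 0.45-interval window.

The tangent construction is used instead of the naive "preceding local
minimum" because a band-limited pulse has truncation ripples in its flat
diastolic tail; under beat-to-beat amplitude jitter the argmin hops
between ripple minima (jumps of ~T/10), which destroys the phase indices.
The tangent fiducial depends on the minimum *level*, which is stable, and
on the upstroke slope, which is steep; in simulation it reproduces
ground-truth onsets to within 0.5 samples at 500 Hz. An upstroke whose
foot-search window would extend before the first sample is skipped — the
foot of a beat whose preceding diastole is not in view cannot be
localized — so a record that begins exactly at a beat onset loses its
first beat.

Quality control drops beats whose period deviates from the record median
by more than 30 % or whose peak-to-trough amplitude deviates from the
median by more than 50 % (both configurable; labels `period_outlier`,
`amplitude_outlier`). Spectra are computed on raw, unfiltered beat
samples; the band-pass exists only for detection.

## Spectral indices

Each beat is resampled to 512 points over [0, period) with a *periodic
cubic spline* and the DFT is taken, so harmonic n is exactly bin n
regardless of beat length; amplitude = 2|Xₙ|/512, phase = arg Xₙ in the
cosine convention, wrapped to (−180, 180]. A cubic rather than linear
interpolant matters: linear interpolation attenuates harmonic n by
sinc²(πn/N), ≈ 2·10⁻³ at n = 10 for ~430-sample beats, while the spline
error is O(h⁴) ≈ 10⁻⁶. Extraction is verified in tests against an
independent trigonometric least-squares fit of the 21-parameter cosine
series to the raw beat samples.

Aggregation across beats uses sample statistics (ddof = 1). Cₙ is averaged
per harmonic; CVₙ = 100·SD/mean of the per-beat Cₙ. Pₙ is the circular
mean; Pₙ_SD is the linear SD after mapping each phase into the 360° window
centred on the circular mean, which equals the ordinary SD away from the
±180° wrap but does not explode when a tight cluster straddles it.

Two Cₙ normalizations are exposed: `"h1"` (percent of the fundamental;
default) and `"sum"` (percent of the total, summing to 100). Under `"h1"`,
C₁ ≡ 100 % and CV₁ ≡ 0 by construction; both are still reported so the
feature vector always has exactly 40 named entries, and the group
comparison marks such constant-equal indices p = 1. Records that fail
segmentation are reported as failures alongside the feature table, never
silently dropped. At least 3 usable beats are required per subject; a zero
mean proportion makes the corresponding CV missing (NaN) with a warning.

### Error budget for phase variability

An onset error Δ shifts harmonic n's phase by 360·n·Δ/T degrees. Residual
foot wander under waveform jitter is ≈ 1–1.5 samples, i.e. ≈ 1.2·n° at
500 Hz and 70 bpm — a genuine property of a moving fiducial, not an
estimator defect. Parameter-recovery checks therefore assert the ±20 %
recovery of a configured 5° phase SD at harmonics 2–4, where this term
contributes < 1/4 of the configured spread, and of a configured 10 %
amplitude CV (time-origin independent) at harmonics 2–6.

## Group comparisons

Per index: unpaired two-tailed Student's t by default (Welch and
Mann-Whitney selectable), pairwise deletion of missing values, at least 3
subjects per group, and the two-band reporting convention p < 0.05 /
0.05 < p < 0.1 / ns. No multiplicity correction by default, matching the
per-index reporting style of the target analysis; Bonferroni and
Benjamini-Hochberg are available. Under identical-configuration null
cohorts the empirical fraction of indices significant at 0.05 is checked
to be 5 % within ≈ 3σ Monte-Carlo error.

## Classification harness

One 40-value feature vector per subject (the variability indices are
already across-beat summaries, so the subject-level vector is the only
self-consistent unit of analysis). Folds are subject-level and stratified:
within each class, subjects are shuffled and dealt round-robin into k
folds with a per-class starting offset, keeping fold sizes and class
balance within ±1 (76 subjects, k = 3 → sizes 26/25/25).

Features are z-scored with statistics fit on the training folds only —
several of the eight families (SVM, MLP, KNN) are scale-sensitive — with a
switch to disable. Hyperparameters follow the reference configuration of
each family (e.g. SVM C = 1, RBF kernel, gamma = "auto"; MLP one hidden
layer of 100, adam, α = 10⁻⁴, 200 epochs; RF 100 trees; KNN k = 5) and
ModelSpec rejects any key outside that set. Per fold: accuracy in percent,
sensitivity = TP/(TP+FN) with class 1 = AD, specificity = TN/(TN+FP),
rank-based ROC AUC of predicted probabilities, and the confusion table;
the report's averages are exact arithmetic means of fold values, rounded
to 2 decimals only at serialization. Balanced accuracy can be derived from
the stored confusion tables. SVM probabilities use Platt sigmoid
calibration of decision values. Model fits are seeded per fold via
`SeedSequence(seed, fold)`.

External cohorts are scored by a single model refit on the full training
table (not an ensemble of fold models), yielding one AD probability per
test subject.

## Probability–MMSE regression

Simple OLS of the raw (untransformed) probability on MMSE via statsmodels,
reporting slope, intercept, R², and the overall F-test at (1, n−2) df —
numerically identical to the two-sided slope t-test, which the tests
assert. Two preset filters: all test cohorts, and community-only with the
young group excluded (replicating age-confound handling by exclusion
rather than covariate adjustment). Requires n ≥ 3 and non-constant MMSE.

## Problem sizes used in the test suite

Shared fixtures use scaled-down cohorts (8 + 8 training subjects, 6/6/4
external subjects, 60 s records; 15 + 15 for the separability check) and
the Type-I calibration uses 25 replicate null cohorts of 12 + 12 subjects
with 40 s records; parameter-recovery checks use single 180 s records
(≈ 208 beats). The acceptance script runs the full default design
(123 subjects, 180 s records). These sizes were chosen so every derived
statistic keeps comfortable Monte-Carlo margins while the suite stays
quick to run.

## Known limitations

- Synthetic effect sizes are not calibrated to clinical discrimination
  levels (see above); cross-validated metrics on the default cohort sit
  near ceiling.
- The `"h1"` normalization makes C₁/CV₁ degenerate; the `"sum"` mode
  avoids this but changes the scale of every Cₙ.
- The intersecting-tangent foot is a different fiducial from, e.g., an
  ECG R-wave gate; absolute phase values are convention-dependent and
  only comparable within one convention.
- Heart-rate variation is white (per-beat i.i.d. period jitter); real
  records carry autocorrelated respiratory sinus arrhythmia.
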