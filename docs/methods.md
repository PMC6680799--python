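# Methods

This note documents the models, conventions and numerical choices behind
`hoglog`, in the order data flows through the package. Everything stated
here is computed by the test suite or the example scripts; nothing is an
empirical claim beyond what the code demonstrates.

## Study design assumed

A two-phase semi-experimental deployment: a baseline ("pre") phase and a
disturbance ("festival") phase of equal length (default 19 + 19 days,
10 Aug – 16 Sep 2016 in the default calendar), with nest monitoring
continuing a few days past the disturbance. Loggers record one triaxial
acceleration burst per minute (100 Hz, 2.5 s = 250 samples per axis; a
2.64-s / 264-sample variant is supported), GPS bursts of five fixes every
five minutes between 19:00 and 07:00, and a daily nest check per animal.
All timestamps are naive study-local time; civil dawn/dusk arrive as an
external table and define the day/night boundary.

## Synthetic data generator

The generator is first-class, tested code; its defaults *are* the study
conditions above. It emulates, per animal:

* **Activity**: a two-level stochastic process. A slow active/quiet bout
  chain (switch rate 0.25/min) follows a nocturnal occupancy profile —
  0.95 inside the nightly activity window (civil dusk + injected delay +
  N(0, 2 min) daily jitter, until 15 min before the next dawn), 0 outside.
  The animal is forced active at the window start and quiet at its end, so
  nightly bouts neither lag the injected onset nor spill past dawn into the
  next dawn-to-dawn day; the night that began the evening before the study
  is included so day 1 is not a cold start. Within each regime a per-minute
  behaviour Markov chain emits the four labels; the quiet regime emits only
  resting postures (immobile, balling) — the animal sleeps in its nest by
  day, which is what makes mean-threshold onset detection meaningful.
* **Waveforms**: immobile = per-animal posture vector + N(0, 0.03 g) sensor
  noise; balling = the same frame rotated by (+50° pitch, +35° roll);
  locomotion = posture + a 1–3 Hz sinusoid with per-axis amplitudes
  0.4 g × (1.0, 0.6, 0.8) and lognormal amplitude jitter; "other" =
  irregular broadband (white + short moving-average) noise at 0.12 g.
  Amplitudes and noise levels are free parameters of the emulation — chosen
  once for clean but not perfect class separation — because no quantitative
  per-behaviour signature figures exist to fit them to.
* **Fast path**: `generate_minutes` emits the per-minute behaviour/aSD
  stream directly (aSD drawn per behaviour consistently with the waveform
  parameters, lognormal jitter σ = 0.12) for analyses that never touch raw
  waveforms; `generate_study`/`write_study` add the full burst tables.
  The full-size default study is ~115 M samples and must be streamed to
  disk (`write_study`); in-memory generation is refused above 30 M samples.
* **GPS**: an Ornstein–Uhlenbeck walk (correlation time 30 min) around a
  per-animal home centre, marginal SD 60 m, evaluated at event times; the
  animal sits at its nest position outside activity bouts. Fixes add
  N(0, 15 m) receiver noise per axis. Injected artifacts are of exactly the
  two kinds the cleaning stage targets: far outliers (1.1–2.5 km from the
  site) and whole-event jumps of 750–950 m (> 2 m/s between events).
  Coordinates are site-local planar metres; geodesy adds nothing testable.
* **Disturbance effects** (festival phase only, each with optional
  between-animal SD): onset delay in minutes; `area_scale` multiplies the
  nightly utilization *area* (movement radius scales by its square root);
  `dfc_noise_gain` g flattens the occupancy profile toward its own daily
  mean, p ← (1−g)p + g·p̄, weakening 24-h coupling monotonically while
  roughly preserving total activity; `male_nest_hazard_mult` multiplies the
  daily nest-change probability (baseline 0.2) for males.
* **Twilight**: a smooth sinusoid in day-of-year tuned to central-European
  civil twilight (dawn ≈ 05:08→06:05, dusk ≈ 20:51→19:46 over the default
  window). It is a template, not an ephemeris — the analysis treats
  twilight as input data.

What the generator does *not* emulate: real hedgehog biomechanics, terrain,
weather, foraging-specific head movement (indistinguishable from locomotion
at the logger position), GPS multipath structure, or barrier-constrained
movement. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated model, not their robustness
to every artifact of field data.

## Feature conventions

Declared conventions where the literature admits variants: SD/variance use
n−1; kurtosis is the raw standardized fourth moment (normal ≈ 3) and
skewness the standardized third, both on biased central moments; the
inverse coefficient of variation is mean/SD, with SD = 0 producing a
missing flag rather than ±∞; pitch = atan2(sx, √(sy²+sz²)) and
roll = atan2(sy, sz) in degrees from the per-burst mean vector (x forward,
z up); the ODBA static/dynamic split uses the whole-burst mean, since a
2.5-s burst is shorter than any usual running-mean window. The spectral
weighted mean autocorrelates the mean-centred axis (biased, normalized,
circular), takes the magnitude spectrum of the autocorrelation, and returns
Σ f·P(f)/Σ P(f) over positive frequencies; a constant signal returns 0 by
convention. Under-length bursts are dropped; over-length bursts are
truncated to the expected count with a warning. Rows with any undefined
predictor are flagged and excluded from classifier training but retained
for the aSD series.

## Classifier

RBF SVM with library-default hyperparameters and per-pair Platt probability
calibration, predictors z-scored by training statistics; no tuning, because
the protocol names none. The 0.7 gate is strict ("exceeds"): max
probability = 0.7 goes to "other". Leave-one-out is per burst; per-group
(per-animal) cross-validation is available. The gate may be applied during
LOOCV scoring (default) or only at deployment (`gated=False`).

## Day windows and filters

Two deliberately different day definitions coexist: DI and activity onset
use the dawn-to-dawn day (civil dawn opens the day), behaviour budgets and
daily ODBA sums use the calendar day 00:00–23:59 with the ≥ 1430-burst
completeness filter (the pipeline scales the threshold as 1430/1440 of the
configured bursts per day). Dawn-to-dawn days whose series ends before the
next dawn are skipped — a truncated night biases DI upward. The aSD
activity threshold is the mean over the animal's full deployment (per-phase
and global variants available); the onset run length k defaults to 1, with
k > 1 available for noisy data.

## DFC numerics

The autocorrelation is the biased estimator computed circularly via the
FFT. By the Wiener–Khinchin theorem the Fourier transform of this ACF *is*
the periodogram of the series, so (a) the spectrum-of-ACF and a direct
periodogram agree to machine precision (a test asserts this), and (b) a
sinusoid whose period divides the window exactly occupies a single bin.
The one-sided *linear* biased ACF was evaluated and rejected: its
triangular taper leaks ≈ 22% of a pure 24-h line's power into non-harmonic
bins, which would cap DFC at ≈ 0.78 for a perfectly entrained series and
contradict the statistic's definition of 1 = maximal synchrony. The tested
periods run from the window length (3 days) down to twice the sampling
interval (2 min); DC is excluded. Harmonic bins are those within half a bin
of 24/k h (k = 1…720); at the default window all 720 lie on exact bins, so
one third of all bins are harmonic — the arrhythmic (white-noise) baseline
of the statistic is therefore ≈ 1/3, and disturbance effects are read as
movement from the entrained value toward that baseline. Power is the
magnitude of the ACF's transform (the power spectral density of the
series). Windows slide by one day and are assigned to their last day; gaps
≤ 5% of a window are linearly interpolated, larger gaps invalidate the
window. An optional Fisher's-g screening (α = 0.05) restricts the ratio to
individually significant components; the default is the unscreened ratio.

## Space use

Cleaning order is fixed: strict 1000-m site-radius filter on fixes, then
per-event averaging, then a single forward pass dropping events whose speed
from the last *retained* event strictly exceeds 2 m/s. The pipeline is
idempotent. KDE50 uses per-axis reference bandwidths h = σ̂·n^(−1/6) (the
two-dimensional Scott/"href" rule restricted to a diagonal bandwidth) on a
200 × 200 grid with a 3-bandwidth margin; the area is the count of
highest-density cells accumulating 50% of the mass times the cell area.
Degenerate point sets floor the bandwidth at 1 m with a warning. Against
the analytic 50% region of an isotropic Gaussian (2π ln 2 σ²) the estimate
carries a small positive smoothing bias (≈ +9% at n = 2000), well inside
the 15% envelope the tests enforce. Per-night KDEs are the primary product
(a per-phase pooled variant is a trivial caller change); bandwidth and grid
are configuration keys.

## Nest survival

Spells are maximal runs of consecutive same-nest days; a differing next-day
check closes the spell with an event, while phase boundaries, gaps in the
checks and monitoring end censor it (phase-boundary censoring keeps each
spell within one phase; assigning whole spells to their starting phase is
the obvious switchable alternative). "Non-festival" pools the baseline and
post-festival days. The Kaplan–Meier estimate comes from lifelines; the
log-rank statistic is computed directly so that it can be reported as a
signed Z = (observed − expected events in group A)/√V with the standard
hypergeometric tie correction, with p from the normal approximation.
Because spell-count and nest-day denominators are both defensible, the
summary reports both.

## Change estimation

Daily values are transformed before differencing — DI → ln(DI + 1 + ε)
with ε = 10⁻⁶ (DI = −1 would otherwise hit ln 0), TSdusk shifted by |min|
to non-negative, ODBA z-scored; applying the transform to the differences
instead is a switch. The full cross product of festival-minus-pre daily
differences per animal feeds the random-intercept model
diff = μ + bᵢ + ε, fit by exact REML: with one variance ratio
ψ = σ²_b/σ²_e the REML criterion profiles to a one-dimensional
optimization, solved to ~10⁻⁸ — a generic mixed-model optimizer stops
around 10⁻⁴ short of the balanced-ANOVA closed form, which the tests use
as the oracle (with statsmodels MixedLM as an independent cross-check).
σ̂²_b at the boundary falls back to a pooled intercept with a flag.

The pairwise differences are not independent: each daily value is reused in
every difference it enters, so an animal's mean difference equals the
difference of its two phase means, whose true replication is
n_eff = 2ab/(a+b) (harmonic mean; 19 for a balanced 19 + 19 design), not
a·b = 361. Shrinkage weights and the conditional (BLUP) prediction
variance, Var = (1−λ)σ²_b + (1−λ)²·Var(μ̂) with
λ = σ²_b/(σ²_b + σ²_e/n_eff), therefore use n_eff. Simulations in the test
suite show this keeps the zero-effect false-change rate near the nominal
5% while preserving detection of heterogeneous (opposite-sign) individual
effects; with the raw count 361 in place of n_eff the same null simulation
flags the majority of animals. A marginal interval (adding the full σ²_b)
remains available as the conservative variant. Significance is "interval
excludes zero", reported per animal and summarised as counts of
decreases / no change / increases per parameter.

Caveat: even with the effective-replication correction the cross-product
design remains a pseudo-replication device; its μ̂ equals the difference of
phase means, and the per-animal intervals inherit whatever day-to-day
autocorrelation the daily metric carries (DFC values of overlapping 3-day
windows, for instance, are serially dependent). Parameters with secular
trends over the study window (e.g. raw daily activity totals as nights
lengthen) will show "changes" that are real trends, not disturbance
effects; the dusk-anchored and normalized metrics are designed to avoid
this.

## Problem sizes used in the tests

The suite runs scaled studies — 1–8 animals, 2–10 days per phase, bursts of
0.1–1 s — chosen so every estimator operates in its intended regime (full
1440-minute days for the completeness filter, ≥ 3 full days for DFC
windows, 8 animals where the per-individual significance pattern is the
assertion) while the whole suite stays fast. Effect-recovery settings:
45-min onset delay recovered within ±10 min; area_scale = 0.5 recovered
within ±20%; dfc_noise_gain = 0.8 yields significant DFC decreases in
≥ 7 of 8 animals; LOOCV recall ≥ 0.9 per class at 40 bursts/class.

## Known limitations

* The SVM gate threshold interacts with calibration quality at small
  training sizes; "other" fractions are not comparable across training-set
  sizes.
* DFC windows containing behaviourally excluded days are interpolated or
  skipped as wholes; no partial-window variant exists.
* The log-rank normal approximation is coarse below ~10 events; the tests
  compare it against an exhaustive permutation mid-p at that scale.
* No covariates (sex, reproductive state) enter the change model; the
  random intercept is the only structure.
* The generator's GPS noise is isotropic white; habitat-dependent error is
  reported in field studies but no error model is applied downstream.
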