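# Methods

`liftsafe` re-implements, as a tested pipeline, an analysis for
discriminating safe (squat) from unsafe (stoop) lifting postures using a
single sternum-mounted inertial measurement unit (IMU). Real recordings
from such protocols are typically private, so the package ships a
synthetic-trial generator that emulates the acquisition protocol; every
downstream stage operates identically on real six-channel CSV recordings.

## Study protocol emulated by the generator

Each simulated subject performs two trials: 20 consecutive liftings at
2.5 liftings/min over 8 minutes, once per posture class. Signals are
six-channel — tri-axial linear acceleration (m/s²) and tri-axial angular
velocity (deg/s) — sampled at 200 Hz by default (the sampling rate is
configurable; the emulated sensor class records at up to 200 Hz, and the
segmentation band-pass requires at least ~2× 50 Hz).

Each lifting contributes a Gaussian-windowed oscillatory burst on all six
channels, dominant on the x (longitudinal/vertical) acceleration axis, on
top of Gaussian baseline sensor noise. Class enters through burst
morphology:

| parameter | safe (squat) | unsafe (stoop) | rationale |
|---|---|---|---|
| acc carrier | 7.0 Hz | 4.0 Hz | controlled vs slow-jerk lift; drives ZCR/SSC safe > unsafe |
| vel carrier | 6.0 Hz | 3.5 Hz | same, on the gyro channels |
| burst window SD | 0.90 s | 0.55 s | squat lifts are longer and smoother |
| subcarrier (½ carrier freq) | 0 | 0.5 × carrier amplitude | spreads unsafe energy over two spectral lines: higher spectral entropy, lower spectral kurtosis/skewness |
| acc amplitude | 1.2 m/s² | 0.85 m/s² | higher acceleration power for the leg-driven lift |
| vel amplitude | 25 deg/s | 45 deg/s | stoop lifting rotates the trunk much faster |

The subcarrier amplitude stays below half the carrier's, so it broadens
the spectrum without creating zero crossings or slope reversals of its
own (for A·sin(2πft) + B·sin(πft) with B < A/2, the summed derivative
cannot change sign more often than the carrier's).

Cohort heterogeneity: per-subject burst gain U(0.8, 1.2), lifting-onset
jitter SD U(0.5, 1.5) s (clipped at a quarter of the 24-s inter-lift
interval so liftings never merge), accelerometer noise SD
U(0.0015, 0.003) m/s², gyro noise 15× that value in deg/s. The noise
floor is deliberately idealized relative to consumer hardware: the
slope-sign-change count of a sampled waveform is dominated by
noise-induced micro-extrema wherever the deterministic slope per sample
falls below the noise increment, and at realistic noise levels that
artifact — not posture — would control SSC. A slow trunk-tilt bump
(below the 1-Hz high-pass edge) is added for realism but is removed by
the segmentation filter.

Every random draw descends from a single cohort seed; per-subject trial
streams derive from `cohort_seed + subject_id` plus a trial index, so any
subject-trial regenerates independently and byte-identically.

What the generator does **not** model: anthropometric variation, sensor
orientation drift, magnetometer data, gravity components (signals are
burst + noise around zero rather than around ±9.81 m/s²), non-stationary
fatigue effects, or any biomechanical forward dynamics. Passing tests
therefore demonstrate correctness of the *pipeline arithmetic* and the
qualitative class-contrast structure, not classifier performance on real
recordings.

## Segmentation

1. Zero-phase (forward–backward) 4th-order Butterworth band-pass, 1–50 Hz,
   on the x-axis acceleration. Zero-phase filtering is chosen so detected
   boundaries are not phase-delayed before being transferred to the raw
   channels; it doubles the effective filter order.
2. Full-wave rectification, then Savitzky–Golay smoothing with polynomial
   order 4 and frame length 1101 samples (~5.5 s at 200 Hz). Negative
   undershoots of the least-squares fit are clamped to zero; a frame
   longer than the signal is clipped to the largest valid odd length with
   a logged warning (relevant only for short test signals).
3. Threshold intersection: each upward crossing of a per-trial threshold
   opens an ROI, the next downward crossing closes it (a tie counts as
   inside). Runs shorter than 0.5 s are discarded and gaps under 1 s are
   merged, guarding against noise-induced double crossings.

The per-trial threshold defaults to the 0.90 quantile of the smoothed
envelope. The quantile rule operationalizes "an empirical per-subject
threshold": it adapts to each subject's amplitude scale automatically.
The value 0.90 follows from the protocol's duty cycle — bursts elevate
the envelope over roughly 15–20 % of the trial, so quantiles in
≈[0.88, 0.93] sit between the noise baseline and the burst mass, and the
ROI count is stable across that whole band (tested); quantiles at or
below ~0.85 can descend into the baseline and produce spurious runs. A
fixed absolute threshold is available via `threshold_mode="fixed"`.

ROIs are cut from the **original unfiltered** channels; features see raw
waveforms.

## Features

Nine features per channel segment, 54 per lifting (9 × 6 channels):

- **STD**: sample standard deviation, N−1 denominator.
- **MAV**: mean absolute value.
- **PP**: max − min.
- **ZCR**: count of adjacent pairs with a strict sign flip; pairs
  containing an exact zero do not count.
- **SSC**: count of strict interior local extrema; plateaus break runs.
- **P**: mean of the total power spectrum S_i = |X_i|² over all N DFT
  bins (equal to the segment's total energy Σx², by Parseval).
- **SE**: Shannon entropy of p_i = S_i/ΣS, divided by log₂N so it lies
  in [0, 1]; the normalized form is the default because it matches the
  magnitudes such features take in practice (~0.5–0.6), with the raw
  value available via `se_normalized=False`.
- **Kurt**: excess kurtosis of the spectrum values, fourth central
  moment over N·s⁴ minus 3, with the population (÷N) standard deviation
  s of the spectrum. A literal third-power numerator is selectable via
  `kurt_exponent=3` for comparison, but is dimensionally inconsistent
  with the s⁴ denominator and the −3 excess correction and is not used.
- **Skew**: third standardized moment of the spectrum values, population
  denominator.

The spectrum uses all N bins of the unnormalized DFT (no one-sided
folding). Every feature is verified against an independent brute-force
loop transcription at 1e-8 relative tolerance, and against closed-form
hand values; homogeneity (STD, MAV, PP, √P of degree 1) and scale
invariance (ZCR, SSC, SE, Kurt, Skew) are property-tested.

## Paired statistics

For each of the nine features per signal (acceleration, angular
velocity), safe and unsafe values are paired by (subject, lifting index).
Because the published report format is one row per feature per signal
while the dataset has three axes, the three axis values of each lifting
are averaged before testing by default (`axis_mode="x"` tests the
longitudinal axis alone). A Shapiro–Wilk test on the paired differences
(the quantity whose normality the paired t-test assumes) gates the
choice: p ≥ α → two-tailed paired t-test, otherwise two-tailed Wilcoxon
signed-rank. α = 0.05; the 18 tests are deliberately uncorrected for
multiplicity, and the report footer says so. All-zero differences yield
a degenerate p = 1 row with a warning.

Calibration: under a 10,000-replicate null (300 i.i.d. normal paired
differences) the gated procedure rejects at 0.050. Note that the correct
permutation null for this *paired* design is the per-pair label swap
(sign-flip); permuting labels freely within a subject leaves the
subject-level class imbalance correlated across pairs and inflates the
apparent rejection rate.

## Classifier benchmark

Leave-one-subject-out cross-validation: each of the 15 subjects is the
test set exactly once, so within-subject correlation never leaks across
the split. Min-max normalization to [0, 1] is applied to the three
scale-sensitive models (LR, kNN, SVM), fitted per fold on the training
rows only (a whole-table mode exists behind `minmax_scope="global"` for
fidelity comparisons with platforms that normalize up front). The
positive class defaults to `unsafe` — the clinically relevant detection
target — and is switchable.

Fixed hyperparameters (no search is performed): SVM polynomial kernel
(1.489·⟨u,v⟩ + 1.141)^1.734 implemented as a callable kernel (the
non-integer power is well defined because scaled features make the base
positive); decision tree unpruned with ≥5 records per split; gradient
boosting with 149 depth-2 trees at learning rate 0.333; random forest of
52 depth-5 trees with minimum node size 4; logistic regression as plain
gradient descent (constant step 0.516, ≤111 epochs, tolerance 0.004) via
`SGDClassifier` with log loss and no penalty; kNN with k=7; MLP with one
hidden layer of 5 units and at most 60 iterations; PNN as a
dynamic-decay-adjustment Parzen network with θ⁻ = 0.109, θ⁺ = 0.928
(plain Specht mode selectable). The MLP's 60-iteration cap is part of
the benchmarked configuration and is tight enough that the model may
stop before convergence even on trivially separable data; the test suite
verifies the wrapper's correctness with the cap lifted and benchmarks it
with the cap in place.

Seven metrics per fold from the confusion matrix at a 0.5 score
threshold — accuracy, F-measure, specificity, sensitivity, precision,
recall (= sensitivity, reported separately for report compatibility) —
plus AUCROC from the score ranking (midrank ties). Models without a
probability output contribute logistic-squashed decision values, which
preserves the 0.5-threshold/predict equivalence. Fold means ± SD use the
N−1 denominator over the 15 folds. The benchmark is bitwise reproducible
under a fixed seed.

## Information-gain ranking

IG(feature) = H(Y) − Σ_b p(b) H(Y|b), base-2, with the feature
discretized into 10 equal-frequency bins (ties assigned to the lower
bin). The bin count is a genuine free parameter — IG magnitudes depend
on it — hence it is config-exposed; 10 bins on 600 rows leaves ~60 rows
per bin, enough for stable conditional entropies. Equal-frequency
binning makes the ranking invariant under strictly monotone transforms.
IG is computed once on the full dataset (matching a single published-style
ranking figure, not per fold). Aggregate shares per axis, per signal and
per feature family each divide the summed member IG by the total over
all 54 features.

## Problem sizes and numerical choices

The default cohort (15 subjects × 2 trials × 20 liftings at 200 Hz,
8 min) yields the canonical 600 × 54 table and runs end to end in well
under a minute; the test suite uses this full default cohort once (as a
shared fixture) plus smaller cohorts for orchestration tests. Degenerate
inputs are errors, not NaNs: a flat spectrum (s = 0) rejects the
spectral moments, an all-zero spectrum rejects SE, segments shorter than
8 samples reject spectral features, and these errors carry the
(subject, lifting, channel) identity. A detected-ROI table, feature
table, statistics report, per-fold metric log and ranking are all plain
CSV/JSON; the orchestrator's manifest records the config snapshot, seed
and SHA-256 of every artifact, and a rerun with the same config is
byte-identical (manifest timestamps aside).

## Known limitations

- The generator's class contrast is built in by construction; benchmark
  scores on synthetic cohorts are near-ceiling and say nothing about
  effect sizes in real populations.
- The DDA-PNN kernel-width schedule and the MLP activation/convergence
  details of the platform the hyperparameters originate from are not
  public; the implementations here are standard (Berthold–Diamond DDA,
  ReLU/adam MLP) and documented rather than bug-compatible.
- Spectral features on variable-length ROIs are length-dependent (ZCR
  and SSC are counts, not rates); this mirrors the emulated analysis and
  is deliberate.
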