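# Methods

## Scope and data model

The package operationalises a POAF-prediction analysis working from
long-term single-lead preoperative ECG plus a clinical covariate table.
Since no patient recording is distributed, all development and testing runs
on synthetic data with exact ground truth; this note states what the
generator emulates, how each stage works, which parameters matter, and what
the tests consequently do and do not demonstrate.

## Synthetic ECG generator

Each beat is the sum of three smooth lobes on a zero baseline: P, QRS and T,
rendered as sin² ("raised-cosine") arcs. The shape choice is deliberate —
the feet of a sin² lobe leave and rejoin the baseline tangentially, so
"onset/offset at the intersection with the isoelectric line" is geometrically
well defined, which is the measurement rule the delineator implements.

Per-beat quantities:

* R-peak times follow a Gaussian RR walk (default 1000 ± 40 ms, floored at
  300 ms).
* P duration is drawn per beat from Normal(μ, σ) truncated at 40 ms;
  (μ, σ) are patient-level parameters. The truncation floor prevents
  degenerate zero-width waves.
* The P apex sits at a configurable fraction of the duration (default 0.5);
  the rise and fall are separate sin² half-arcs, so asymmetric waves are
  supported. "First peak" is therefore the lobe apex.
* Geometry: the PR interval (P onset → QRS onset, default 180 ms) is
  extended per beat when a wide P would leave less than 50 ms of flat PR
  segment; that segment is what the delineator uses to estimate the
  isoelectric level. QRS is a 90 ms lobe of 1 mV, the T wave a 200 ms lobe
  of 0.25 mV starting 100 ms after the QRS.
* Noise: baseline-wander sinusoid (default 0.3 Hz), powerline sinusoid
  (50 Hz) and white noise, each with independent amplitude; all zero by
  default. `white_sd_for_snr` converts a target SNR in dB into a white-noise
  SD against a given clean record. No recording-specific noise
  characterisation exists to calibrate against, so noise levels are free
  parameters of each experiment.

Sampling rate defaults to 500 Hz (2 ms per sample) and is required to be
≥ 250 Hz so millisecond-scale features stay meaningful. Exact per-beat
onset/peak/offset times and R-peak times are returned as `SimTruth`.

Patient-level P-wave distributions per outcome group mirror the observed
group structure: mean beat-to-beat P duration drawn from N(133, 23) ms in
the no-POAF group and N(141, 25) ms in the POAF group; beat-to-beat SD from
N(15, 7) and N(19, 11) ms (floored at 2 ms).

What the generator does **not** emulate: AF rhythm itself, ectopy, biphasic
or notched P waves, electrode motion artifact bursts, respiration-linked
amplitude modulation, or any joint correlation structure between clinical
covariates. Passing tests demonstrate correctness of the measurement and
modelling machinery under these idealised morphologies, not field
performance on patch recordings.

## Clinical cohort generator

Continuous covariates are drawn Normal(mean, SD) per group, right-skewed
operative times lognormal matched to the group median and IQR
(σ = ln(q3/q1)/1.349), binary covariates Bernoulli; all independent within
group, which is a documented simplification. The P-wave summary features
can be drawn directly at patient level for model experiments; there Pmax
and PWd are sampled from their group distributions and Pmin derived as
Pmax − PWd, so the dispersion identity holds row-wise and all three group
means are internally consistent. The implied Pmin SD (≈ 42 ms) is larger
than the observed ≈ 22 ms — the published trio cannot be matched exactly by
independent draws; means were prioritised because the downstream checks
(identity, t-battery, model ordering) are mean-driven.

## Preprocessing

Low-pass then high-pass 4th-order Butterworth, each applied
forward–backward (`sosfiltfilt`), so the chain is zero-phase: filter delay
is corrected exactly and passband tones keep their timing (cross-correlation
peak at lag 0, asserted in tests). Defaults 40 Hz / 0.5 Hz are the standard
ambulatory P-wave band; the vendor chain this stands in for is unspecified,
so both cutoffs and the filter order are configurable rather than inferred.
Smoothing is a centred moving average (default 20 ms → 11 samples at
500 Hz) with reflect padding; window 0 is the identity. No stage changes
the sample count.

## QRS detection

Derivative-energy detector: band-pass 5–18 Hz, differentiate, square,
150 ms moving-window integration, peak picking above 0.25× the 95th
percentile of the integrated energy with a 200 ms refractory period, then
refinement to the extremum of the band-passed signal. QRS onset — needed
only to anchor the P search window — is where the 25 ms energy envelope
falls below 5% of its local maximum (≤ 120 ms before R). A flat record
returns an empty annotation with a warning.

## P-wave delineation

Per beat, inside a window of 350 ms ending 40 ms before QRS onset:

1. **Isoelectric level**: median of the PR gap segment; its MAD gives a
   local noise estimate. Record polarity is the sign of the median per-beat
   extremum, so uniformly inverted leads delineate correctly.
2. **First peak**: dominant extremum of the polarity-corrected,
   baseline-subtracted window. Beats whose amplitude is below the floor
   (default 0.05 mV) or below 4 noise SDs are marked invalid.
3. **Onset/offset**: a threshold walk from the peak to
   max(2·noise SD, 2% of amplitude) gives initial crossings; a
   least-squares fit of a smooth asymmetric lobe (sin² rise/fall with free
   onset, rise, fall and amplitude, plus a constant local-baseline term)
   then refines them, and the fitted lobe's baseline intersections are
   reported. The model is convolved with the conditioning chain's
   moving-average kernel, because smoothing widens a wave's foot by half a
   window per side and a crossing rule applied directly to the smoothed
   trace would be biased outward by that amount; the delineator therefore
   takes the smoothing window as a parameter (default matching the chain's
   20 ms).

The refinement is the package's answer to a numerical fact: near a
tangential foot the signal rises only quadratically, so at realistic noise
levels (SNR 20 dB leaves ≈ 6 µV RMS in-band after conditioning) the
per-sample SNR in the foot region is ~1–3 and any purely local crossing
rule has multi-millisecond jitter and bias. Fitting the whole lobe pools
the steep, information-rich flanks into the edge estimate. Measured on
synthetic ground truth: duration error ≤ 2 samples for 100% of clean beats
(MAE ≈ 0.8 ms) and MAE ≈ 3.4 ms at SNR 20 dB. The cost is a shape
assumption — a smooth unimodal lobe — which the generator satisfies by
construction; on real data with notched or biphasic P waves the fit would
be mis-specified, and validity flags rather than accuracy guarantees apply.

Quality control replaces manual over-reading with rules: drop beats that
are invalid, outside 40–400 ms duration, or below the amplitude floor;
flag the patient as excluded when fewer than half the beats survive
(threshold configurable).

## Features

The seven parameters are computed over all QC-passed beats of the analysis
window (default: the whole record; segment selection is a parameter because
the upstream convention is not fixed). SDs are sample SDs (ddof = 1).
Pstd and Pptstd are reported in ms like the other parameters. The identity
PWd = Pmax − Pmin holds per patient by construction and is asserted, as is
its group-mean consequence mean(PWd) = mean(Pmax) − mean(Pmin), which also
reproduces the published group rows (167 − 105 = 62 ms; 184 − 104 = 80 ms).

## Statistics

Normality is declared per variable, not tested. Pooled-variance (Student)
*t*-tests are used rather than Welch: applied to the published n/mean/SD
triplets, the pooled form reproduces the published p-values within ±0.005
(age 0.0119, GFR 0.0005, urea 0.0121, Pmax 0.0190, Pstd 0.0305, PWd 0.0072),
which settles the choice empirically. Chi-square is computed without
continuity correction (the published sex comparison, 0.314, matches only
then); Fisher's exact test replaces it when any expected 2×2 cell is below
5. Mann–Whitney U (two-sided) serves skewed operative-time variables. No
multiple-testing correction is applied anywhere, matching the analysis
being reproduced.

## Risk models

Logistic models are fitted by maximum likelihood with an intercept.
Perfect separation is flagged but not fatal (the probability ranking is
still usable for ROC); constant predictors and singular designs are hard
errors. AUC is computed by the Mann–Whitney identity with ties counted ½,
and its 95% CI by DeLong's placement-variance method — chosen because it is
the standard single-sample ROC CI; the scikit-learn AUC serves as an
independent cross-check in tests, never as the implementation. Mechanical
ventilation time is a postoperative covariate used as a predictor; the
package keeps it for fidelity but emits a temporal-leakage warning.

SVM protocol: the minority class (POAF) is split 7:3 with floor() on the
training side (28 → 19 + 9, reproducing the published counts); an equal
number of majority patients forms the balanced training set; scheme A tests
on all remaining patients (47 + 9), scheme B on a class-balanced random
subsample (9 + 9). Features are z-scored with parameters fitted on the
training folds only (a stated deviation: standardisation is not part of the
source protocol but is required for a meaningful RBF kernel). The RBF
kernel is assumed because a γ hyperparameter implies it. Grids default to
log-spaced C ∈ 10^[−2,3] and γ ∈ 10^[−3,2] at 6 points per decade; ties
break toward smaller C then smaller γ via ascending scan with strict
improvement. Everything is deterministic given (data, grids, seed).

## Numerical and scale choices

Test and acceptance problem sizes are chosen so the whole suite runs in a
few minutes on one CPU: 300-beat records for delineation accuracy, 80 s
records × 60 patients for end-to-end parameter recovery, 20 s records × 94
patients for the feature-matrix construction, 200 cohort replicates for the
model-ordering check. Nothing in the feature mathematics depends on record
length; long-term duration is a parameter, not an assumption. Sample
indices are 0-based with half-open windows; exported times are milliseconds
from record start; fractional fitted edges are rounded to the nearest
sample.

## Known limitations

* Independent covariate draws ignore real clinical correlations (age–GFR,
  LA–valve disease), so multivariable coefficients on synthetic cohorts are
  cleaner than reality would allow.
* The delineator's lobe model matches the generator's morphology; accuracy
  numbers are upper bounds for real patch data.
* Detection-rate and split arithmetic are bookkeeping on published counts —
  they validate the pipeline's accounting, not the clinical finding.
* Published test-set SVM accuracies and tuned (C, γ) depend on the actual
  patient data and one undisclosed random split; they are not reproducible
  from synthetic cohorts and are deliberately not asserted. The directional
  claim — the clinical+ECG model does not underperform the clinical model —
  is asserted distributionally instead (≥ 80% of 200 replicates; observed
  100%).
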