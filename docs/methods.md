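# Methods

`pursuitspect` quantifies smooth-pursuit integrity from consumer-grade video
oculography. The measurement chain is: per-frame eye/iris facial landmarks →
normalized iris trajectory → time–frequency analysis (ConceFT) → 28 spectral
band features → group statistics, classification, and severity estimation.
This note records the model, the parameters that matter, and the places where
the design was genuinely open.

## The task and its signal

The subject follows a dot that sweeps horizontally across a screen at
constant speed (16° peak-to-peak, 2 cycles per trial, 2.5 s dwells at the
extremities; ~11°/s in trial T1, ~16°/s in trial T2) while a 240 fps camera
records the face. Healthy pursuit tracks the ramps smoothly; cerebellar
disease breaks pursuit into a staircase of catch-up saccades recurring at
roughly 1.5–2.5 Hz. The analysis detects that rhythm as a shift of relative
spectral power into the 1.5–2.5 Hz band.

## Trajectory extraction

- **NIC.** The normalized iris center is the iris-center landmark minus the
  midpoint of the two eye-corner landmarks; common head translation cancels
  exactly. By default the offset is further divided by the per-frame
  inter-corner distance, which removes camera-distance dependence and makes
  signals dimensionless (`nic_scaling = false` gives raw pixels). The
  relative band features are scale-invariant either way. The left eye is the
  default channel; neurodegenerative ataxias show no systematic left–right
  asymmetry, and only the horizontal coordinate is analyzed (the vertical
  channel has far worse signal-to-noise on a horizontal task).
- **Blinks.** Detected by the eye aspect ratio EAR = (‖p2−p6‖ + ‖p3−p5‖) /
  (2‖p1−p4‖), thresholded at 0.2 with 3 frames of padding on each side
  (both exposed in config; the threshold is the conventional operating point
  for this statistic, roughly two-thirds of a typical open-eye EAR of 0.3).
  Blink frames and undetected frames are bridged with a cubic spline through
  the surrounding valid samples so the spectral transform sees a gapless
  series, but they stay flagged and contribute nothing to features. Gaps
  touching the recording boundary are filled by holding the nearest valid
  value; cubic extrapolation is wild there.
- **Low-pass.** Order-4 Butterworth at 8 Hz, applied forward–backward
  (zero phase, so saccade timing is not skewed). After the 8 Hz cutoff the
  series is decimated to 60 Hz for the spectral stage; the band of interest
  ends at 8 Hz, so 60 Hz sampling is generous, and the decimated features
  agree with full-rate features to ~2% (tested).
- **Detrending.** A repeated-median regression trend (slope = median over i
  of the median over j≠i of pairwise slopes; intercept = median of
  x_j − slope·t_j) is estimated in a centered 1 s window at every sample and
  subtracted. The estimator has a 50% breakdown point, so residual blink
  spikes and saccade steps do not drag the trend. The 1 s window was chosen
  to pass sub-1 Hz content (head drift, the stimulus-following ramp) while
  transmitting 2 Hz near-unit gain; measured transmission at 1.5/2.0/2.5 Hz
  is ≈1.3/1.0/0.74 — the filter is nonlinear and not flat, but it is fixed,
  identical for all subjects, and preserves the contrast of interest.
  Shorter windows (≤0.6 s) attenuate 1.5 Hz badly and were rejected.

## ConceFT and the 28 features

The synchrosqueezing transform (SST) computes a short-time transform with a
window g and its derivative g′, estimates each coefficient's instantaneous
frequency as f − Im(V_g′/V_g)/2π, and reassigns squared magnitude to that
frequency on a fixed grid. ConceFT repeats this for random unit-norm complex
combinations of J orthonormal Hermite windows and averages the squeezed
power, trading a slightly broader clean-tone ridge for a large reduction in
estimator variance. With 30 projections, band features across independent
projection seeds differ by ~0.1% relative L1 on a stationary tone; on
broadband saccadic-pursuit signals the seed-to-seed variation is a few
percent, shrinking with the square root of the projection count. Everything
downstream (group contrasts, classifiers) operates on one fixed projection
seed per configuration, so this Monte-Carlo wobble never mixes into
between-subject comparisons.

Defaults (all in `PipelineConfig`): 2 Hermite tapers, 30 projections, 2 s
window (121 samples at 60 Hz) with half-time-bandwidth 6, hop 5 samples
(12 ms), frequency grid 0.1–8 Hz in 0.05 Hz steps (159 bins), squeeze
threshold 1e-8 of the maximum magnitude (a numerical floor only). The
Hermite family is re-orthonormalized by QR after sampling so discrete inner
products are the identity to machine precision; derivatives use the analytic
Hermite recurrence mapped through the same change of basis.

A time frame is excluded from every feature if a blink-interpolated or
missing sample lies within 0.65 of the window half-support of its center —
beyond that radius the tapers have decayed below 1e-3, so leakage from
masked samples is negligible, and excluding the full support would discard
~2 s of data per blink for no benefit.

Features: the 1–8 Hz range is split into 14 half-Hz bands; per band the sum
and the variance of power over (band bins × valid frames) are computed, sums
normalized by the total sum, variances by the total variance: 14 "Sum" + 14
"Var" features per trial, plus the element-wise T1/T2 average. The variance
pools over both frequency bins and time frames within the band; pooling over
time only (variance of per-frame band sums) is a defensible alternative, and
the pooled choice is documented here precisely because the convention is
otherwise ambiguous. The 1.5–2.5 Hz *band-power fraction* — band power over
total 0.1–8 Hz power, valid frames only — is the univariate summary used in
group contrasts.

## Group statistics

Two-sided Mann–Whitney U with the rank-biserial correlation
r = 2U/(n₁n₂) − 1 as effect size. For n₁+n₂ ≤ 12 the p value is an exact
permutation enumeration over all group assignments (valid under ties);
larger samples use the tie-corrected normal approximation with continuity
correction. The 0.05 Hz frequency sweep reports raw per-frequency p values —
deliberately no multiple-testing correction, since the sweep is exploratory
and the band decision is made once.

## Classification

Leave-one-out CV: per fold, features are standardized with training-fold
statistics (a global-standardization flag reproduces the alternative reading
of the protocol, at the cost of mild leakage) and a linear-kernel SVM
(C = 1.0 fixed, no hyperparameter search, class weights inversely
proportional to class sizes) is fitted; the held-out subject's signed
decision value is pooled into one ROC. AUC is trapezoidal and equals the
Mann–Whitney pair-counting probability exactly. The "optimal" point
maximizes Youden's J with ties resolved toward sensitivity; fixed operating
points report specificity at the first threshold reaching ≥80% true
positives and sensitivity at the last threshold with ≤20% false positives.
A 4-feature linear-discriminant variant uses only the Sum and Var features
of the 1.5–2 and 2–2.5 Hz bands.

## Severity estimation

Severity labels (a 0–2 oculomotor subscore in half-point steps) are ordinal
and noisy, so the estimator learns orderings: every unordered pair of
subjects with unequal scores contributes its feature difference and the
indicator of which member is more severe; both orderings are included
(delta, label) and (−delta, 1−label), which forces the optimal intercept to
zero, so the intercept is omitted. An L1-regularized logistic model
(inverse-regularization C = 1.0, liblinear, tol 1e-6, coordinate order
pinned for determinism) is fitted once per held-out subject on the pairs
among the others, with features standardized by the others' statistics; the
subject's estimate is w·x on that standardized scale — a native linear
scale, not rescaled to [0, 2]. Note what held-out construction does and does
not buy: subject i's *own* fold (weights and standardization) is exactly
blind to x_i, but subject i legitimately participates in every other
subject's training pairs, so perturbing one subject does move other folds.

## The simulator

The generator produces what the analysis assumes about real recordings:
per-frame landmark tracks at 240 fps on the clinical stimulus, with

- pursuit gain g ∈ [0, 1] (eye velocity / dot velocity during tracking);
- catch-up saccades as 50 ms linear ramps that cancel the accumulated
  position error, triggered by a gamma renewal process (mean rate
  `catchup_rate_hz`, shape `catchup_regularity`, default 4) whose clock runs
  only while the dot moves. Shape 1 recovers a Poisson process, but a Poisson
  impulse train has a flat spectrum and concentrates no power at the saccade
  rate; real catch-up saccades have a refractory period and a preferred
  tempo, and shape 4 (interval CV 0.5) reproduces the 1.5–2.5 Hz
  concentration that the analysis targets;
- a fixation-acquisition saccade ~200 ms after the dot stops, without which
  a low-gain eye would sit parked short of the target through each 2.5 s
  dwell, injecting artifactual low-frequency error power;
- optional nystagmus sinusoid and Gaussian gaze noise;
- landmark rendering at 2 px/deg with a 40 px eye, open-eye EAR 0.3,
  common-mode sinusoidal head drift (shared by all landmarks, hence
  cancelled by the NIC) and independent per-landmark jitter;
- Poisson blinks (default 0.2 Hz, 0.3 s) that collapse the eyelids to a
  tenth of the open aspect ratio and throw the iris landmarks off by a
  configurable spike, with ground-truth intervals returned.

All randomness flows through `numpy` generators derived from one profile
seed; identical seeds give bit-identical tracks.

The cohort conditions used by the tests and the acceptance script are:
saccadic subjects g = 0.6, rate 2 Hz; smooth subjects g = 1, rate 0; both
with 0.2 Hz blinks, 2 px drift, 0.1 px jitter, 0.05° gaze noise; 30 subjects
per group on the T1 trial (the T2 trial behaves equivalently and is
exercised in the trial-averaging paths). The severity benchmark plants a
linear score signal in the four 1.5–2.5 Hz feature columns of a 40-subject
cohort with noise SD 25% of the effect range.

What the simulator does **not** emulate: photometric video content and
landmark-detector failure structure (detector dropouts are modeled only as
missing frames), head rotation (only translation, which the NIC cancels),
vertical eye movements, dysmetric saccade dynamics, and the heterogeneity of
real clinical populations. Passing tests therefore demonstrate that the
pipeline recovers the mechanisms it models — not that clinical effect sizes
(reported on a private patient cohort) are reproduced. Those clinical
figures are reference behavior only.

## Numerical choices and degenerate inputs

- Frequency-grid bins are assigned by nearest-neighbor rounding of the
  instantaneous-frequency estimate; estimates outside the grid are dropped.
- Band membership is lo ≤ f < hi, with the last band closed at 8 Hz.
- Zero total power, all-masked signals, empty groups, single-member classes,
  coincident eye corners and non-monotone timestamps raise typed errors
  (`pursuitspect.errors`) rather than propagating NaNs.
- Problem sizes in the test-suite and acceptance runs (30/30 simulated
  subjects, 40-subject severity cohort, 15 s single-trial signals) are the
  package's study conditions; they keep a full acceptance run in the
  low minutes on one CPU while leaving every statistical margin wide.

## Known limitations

- The repeated-median filter's gain is not flat across 1–3 Hz (see above);
  band features are comparable across subjects but are not calibrated power
  ratios of the raw eye movement.
- ConceFT here is the first-order, Hermite-taper variant; no second-order
  synchrosqueezing, no wavelet variant, no chirp-rate estimation.
- The Mann–Whitney exact path enumerates assignments only up to n₁+n₂ = 12;
  beyond that the normal approximation is used even when ties are heavy.
- Severity estimates are relative (linear-scale projections); mapping them
  onto the clinical 0–2 scale would require an extra calibration step that
  the protocol deliberately omits.
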