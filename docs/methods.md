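# Methods

This note records the models, numerical choices and known limitations of
the `trunkgait` pipeline, in the order data flows through it.

## Sensor model and orientation

Recordings are a seven-column CSV (time, three accelerations, three angular
velocities) with a JSON sidecar declaring units and sampling rate
(default 200 Hz; acceleration in m/s² or g, gravity constant 9.80665 m/s²).
Rows containing NaN are dropped with a logged count; more than 1 % dropped
raises a warning.  The inferred sampling rate (median Δt) must agree with
the declared rate within 5 %.

Tilt correction assumes the only persistent acceleration is gravity.  Each
channel is low-pass filtered (4th-order zero-phase Butterworth, 0.1 Hz) and
averaged over a 30 s window; because a zero-phase filter at 0.1 Hz has edge
transients on the scale of seconds, the filter is applied to the whole
recording and the averaging window is taken from the interior.  The mean
vector is aligned with the vertical axis by two successive rotations —
about the mediolateral axis (sagittal tilt), then about the anteroposterior
axis (frontal tilt) — giving interpretable tilt angles rather than an
opaque least-squares rotation.  The gravity magnitude estimated from this
window is subtracted from the vertical channel.  A mean acceleration below
0.5 g means there is no usable gravity reference and is an error.
Residual yaw about the vertical axis is unobservable from gravity and is
**not** corrected; the nominal mounting orientation disambiguates AP from
ML.  This is a known limitation of single-sensor tilt correction.

## Step events and truncation

The dominant step frequency is the largest periodogram peak of the AP
acceleration in 1–3 Hz; absence of a clear peak (less than 5× the median
broadband level) is reported as "no locomotion detected".  Peaks are then
found on a low-passed copy of the AP signal (cutoff 2.5× the step
frequency, so broadband noise cannot fabricate or displace peaks) with a
minimum inter-peak distance of half a step period and prominence 0.3 ×
SD(AP) (configurable).  Peak positions are refined to sub-sample precision
by a parabolic fit through each peak and its neighbours; without this, the
sample-grid quantisation of stride boundaries places a floor of ≈ 0.08 per
stride under the Lyapunov estimate of even perfectly periodic signals.
A single lower-back sensor cannot label left versus right, so strides are
defined by step parity from the first detected step; all downstream metrics
are parity-invariant.  Quality control is automatic: the fraction of
inter-step intervals deviating more than 40 % from the median is recorded,
and above 5 % the recording is flagged.

All recordings are truncated to exactly 300 strides (configurable), which
fixes the data length entering the symmetry and stability estimators; a
recording with fewer strides is a hard error naming the shortfall.

## Symmetry

Step and stride symmetry are the dominant peaks of the unbiased
autocorrelation (sum at lag m divided by N−m, normalised at lag 0) of each
mean-centred acceleration axis, searched within ±25 % of the event-derived
mean step and stride lags.  Ties go to the smallest lag.  A window with no
local maximum leaves that outcome missing (NaN + flag) rather than forcing
a value — with real cohorts this is what produces slightly different
per-outcome sample sizes.  The estimator is amplitude-invariant and is
checked against a direct O(N·maxlag) summation to 1e-12.

## Local dynamic stability

Each axis is time-normalised to 100 samples per stride (cubic spline per
stride, using the sub-sample stride boundaries), so the exponent is
expressed per stride and is insensitive to stride-duration differences
across participants.  Delay embedding: the delay is the first local minimum
of the average mutual information (64-bin histogram estimator, searched up
to two step periods; fallback a quarter step period with a warning), and
the dimension is the smallest d ≤ 10 whose false-nearest-neighbour fraction
(Kennel criterion, Rtol = 15, Atol = 2) falls below 10 % (fallback d = 5,
the expected outcome for noise-dominated series).  Selection runs on the
first 5000 samples; the embedding is selected once on the vertical axis and
reused for ML and AP, which share the gait dynamics' time scales.

For every embedded point the nearest neighbour with temporal separation
greater than one stride (Theiler window, 100 samples) is found with a
KD-tree; the mean log Euclidean distance between pairs is tracked densely
through the fit range and at every tenth sample out to 10 strides.  λ is
the least-squares slope of that curve over 0–0.5 stride — the short-term
exponent conventional in gait stability work — and the whole computation is
deterministic for a given series.  Fewer than 100 valid neighbour pairs is
an error.

For benchmarking against low-dimensional chaos (the Lorenz system), the
slope is taken over the 0.5–2.0 time-unit range instead: for a noise-free
flow the first half time-unit of the divergence curve reflects the
alignment of neighbour vectors with the most expanding direction, and the
exponential regime that matches the true exponent (two-trajectory
perturbation-growth value ≈ 0.91) lies after it.  Gait signals, whose
divergence saturates within a stride or two, are in the opposite regime,
which is why the short-term window is the right default there.

## Smoothness

SPARC follows the published spectral-arc-length procedure: magnitude
spectrum on a zero-padded FFT (next power of two ≥ 16×N), normalised by its
maximum, restricted to [0, fc] with fc = 10 Hz, adaptively cut at the
outermost frequencies where the normalised magnitude still reaches 5 % of
the peak, and the value is the negative arc length of the spectrum over the
cutoff-normalised frequency axis.  The spectrum is normalised by its
maximum (not the DC value) because angular-velocity channels are near
zero-mean.  Default mode computes one value per axis over the whole
300-stride bout; a windowed alternative (`mode="per_stride"`, consecutive
windows of ≥ 2 s of strides) is provided.

**Known limitation — absolute level.**  For a long zero-mean oscillatory
signal the spectrum is a line spectrum whose interior dominant peak alone
contributes ≈ 2 to the arc, and the many resolved harmonics and noise-floor
wiggles add more, so whole-bout per-axis SPARC values land near −5 to −15,
not near −1.5 as published healthy-adult reference tables report.  Values
of that magnitude are only attainable when the spectrum is DC-dominated
(speed-like, non-negative input) or heavily smoothed — an implementation
detail reference studies do not print.  `trunkgait` keeps the published
formula and treats SPARC comparatively: it is amplitude- and
shift-invariant, equals an independent arc-length summation to 1e-9, and
responds strictly monotonically to injected high-frequency power.  Note the
adaptive 5 % cutoff means band-limited power below that threshold is
ignored by design, so the monotone response begins once injected power
crosses the threshold.

## Covariates

IPAQ (long form) scoring: MET-min/week per intensity = coefficient × days ×
minutes summed over the four domains, with the standard coefficients 8.0
(vigorous), 4.0 (moderate) and 3.3 (walking); standard cleaning caps
implausible daily totals at 960 min (flagged) and zeroes bouts under
10 min.  Categories use the official long-form rules (high: ≥ 3 vigorous
days and ≥ 1500 MET-min/week, or ≥ 7 active days and ≥ 3000; moderate:
≥ 3 × 20 min vigorous days, or ≥ 5 × 30 min moderate/walking days, or
≥ 5 active days and ≥ 600 MET-min/week; otherwise low), isolated in one
function.

Hip strength: two maximal trials per side per muscle group; the higher
trial is the side maximum, MS_average is the mean of the two side maxima
and MS_diff their absolute difference (sign is meaningless without
dominance information).  A missing side leaves the bilateral summaries
missing-flagged.

## Cohort statistics

All models are ordinary least squares (via statsmodels) on complete cases
per outcome.  Gender enters as a binary indicator; no interactions.

- **Age models**: outcome ~ age + gender + BMI, with age² added only when
  the nested F-test is significant at α = 0.05 (a numerically perfect
  linear fit skips the test).  Reported R² is adjusted (it can be
  negative); RMSE is the residual standard error; the F and p refer to the
  age terms as a block over the covariate-only model.
- **ANCOVA**: age-decade factor plus covariates; partial sum of squares for
  the group effect; ω² = (SS_group − df·MS_error)/(SS_total + MS_error),
  which is slightly negative near the null by construction.  The 95 % CI
  is a percentile interval over 2000 stratified bootstrap replicates
  (resampling participants within their age decade), seeded.
- **Post hoc**: covariate-adjusted pairwise contrasts of the six decade
  means from the model covariance; p_bonferroni = min(1, 15 · p_raw).
- **ΔR² blocks**: MET, MS_average and MS_diff are added one at a time
  (never jointly — they are intercorrelated) to the base model; ΔR² is on
  unadjusted R² of nested fits (hence ≥ 0) and significance is a Gaussian
  likelihood-ratio test with 1 df.  A block collinear with the base model
  logs a warning and yields ΔR² ≈ 0.
- **Muscle-group models**: the per-group strength column joins the base
  model; the table reports coefficient, p, sign and a significance flag,
  with all-missing columns flagged rather than raised.

## Synthetic data

The signal generator synthesises trunk signals on a jittered stride-phase
clock rather than simulating musculoskeletal dynamics: that is sufficient
to endow the signals with exactly the statistical structure the metrics
measure, with every property controllable.

- VT and AP acceleration are dominated by the step harmonic (2 cycles per
  stride) with a smaller 4-cycle harmonic; ML carries both sway components
  with the step harmonic dominant, so its step-lag autocorrelation peak is
  positive as in healthy-adult reference cohorts.  Odd (stride-frequency)
  harmonics in VT/AP encode residual left/right difference and scale away
  as the gait becomes perfectly symmetric.
- `asym_alpha` attenuates every second step through a smooth
  stride-periodic envelope, lowering step symmetry while leaving stride
  symmetry untouched.
- `stride_time_jitter_sd` drives a bounded random walk on stride onsets
  **and** on the within-stride timing of the contralateral step, and a
  proportional slow stride-amplitude wander.  Onset jitter alone would be
  removed again by per-stride time normalisation; it is the within-stride
  timing and amplitude wander that perturb the normalised waveform and
  raise λ, which is also how the three variability expressions co-occur in
  real gait.
- `noise_sd` adds white accelerometer noise (fraction of channel SD);
  `gyro_hf_power` injects 6–12 Hz band-limited power into the angular
  velocity; gravity and a configurable mounting tilt are applied last so
  the output is a raw sensor-frame recording.  Ground-truth step times are
  returned for detector validation.

Defaults (`calibrate_default_adult`: step 1.9 Hz, 330 s, α = 0.88, jitter
25 ms, noise 0.18, HF 0.35, tilt 5°/2°) were chosen with
`scripts/calibrate.py` so that multi-seed pipeline outputs sit inside the
healthy-adult reference bands for vertical step symmetry (≈ 0.84), stride
symmetry (≈ 0.93), and stability (λ ≈ 1.37 per stride); mediolateral λ
(≈ 0.89) sits at the lower edge of its band, and smoothness is outside the
published band for the structural reason above.

What the generator does **not** emulate: turning or stopping segments,
speed drift, posture-driven low-frequency content, sensor bias and
saturation, and any pathology.  Tests passing on synthetic signals
demonstrate the estimators' correctness and sensitivity, not their
robustness to those real-world artefacts.

The cohort generator draws ages uniformly within six decades (15 per
decade, n = 90), gender with P(F) = 0.6 and BMI ~ N(24.5, 3.6²) truncated
to [16, 40], and sets each outcome to its generating age model (defaults:
the packaged healthy-adult linear/quadratic models with residual SDs of
0.07–0.18 in outcome units) plus Gaussian noise; optional per-outcome
missingness reproduces per-outcome sample sizes of 88–90.  MET is
log-normal (median ≈ 2000 MET-min/week); per-muscle-group strength declines
mildly with age (−0.4 %/year around 45) with realistic magnitudes per
group; strength and MET effects on outcomes are zero unless configured.

## Problem sizes used in the automated checks

Monte-Carlo checks use 200 replicates for coefficient recovery and
decision-rule calibration (binomial 3σ ≈ ±4.6 points around a 5 % rate);
monotonicity sweeps use 20 seeds per setting with 90–170 s recordings and,
for λ, 150 strides at 50 samples per stride with a fixed (d = 5, τ = 12)
embedding — the reduced resolution changes λ's absolute level but not its
ordering across jitter levels, which is what the sweep asserts.
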