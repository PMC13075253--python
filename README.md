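# trunkgait

Gait quality from a single lower-back IMU during continuous habitual
walking, plus the cohort-level statistics used to study how those measures
change across the adult lifespan.

A sensor worn at the L5/S1 level records tri-axial acceleration and angular
velocity (200 Hz).  From roughly five minutes of self-selected walking,
`trunkgait` derives twelve interpretable per-participant outcomes — step and
stride symmetry, local dynamic stability, and movement smoothness, each in
the vertical (VT), mediolateral (ML) and anteroposterior (AP) directions —
and fits the statistical models that relate them to age, physical activity
and hip muscle strength.  The package is aimed at movement scientists who
want a tested, scriptable version of this pipeline, and it ships a
synthetic-data module so every stage can be exercised with known ground
truth.

## The measures

- **Step / stride symmetry** (Ad1 / Ad2): the dominant peaks of the
  *unbiased* autocorrelation of trunk acceleration,
  `A(m) = [1/(N−m)] Σᵢ x(i)x(i+m) / A(0)`, at the mean step and stride
  lags.  1 = perfectly regular gait; the metric needs no left/right
  labelling.
- **Local dynamic stability**: the maximum Lyapunov exponent λ of the
  per-stride time-normalised acceleration, via the Rosenstein
  nearest-neighbour divergence curve (delay embedding chosen by average
  mutual information + false nearest neighbours; slope over the short-term
  0–0.5 stride range, per stride).  Higher λ = lower stability.
- **Smoothness (SPARC)**: the negative arc length of the normalised,
  cutoff-limited magnitude spectrum of each angular-velocity channel
  (yaw→VT, pitch→ML, roll→AP).  Values closer to zero = smoother motion.

Before any metric is computed the raw signals are tilt-corrected (two
rotations estimated from the gravitational acceleration component), step
events are detected on the AP acceleration with a peak-based algorithm, and
every recording is truncated to a fixed 300 strides so estimates are
comparable across participants.

The cohort layer fits, per outcome: ordinary least squares on continuous
age (gender and BMI as covariates, quadratic age term retained only when a
nested F-test improves fit at α = 0.05, adjusted R² reported); age-decade
ANCOVA with the ω² effect size and a stratified-bootstrap 95 % CI;
Bonferroni-corrected pairwise group contrasts; incremental ΔR² blocks with
likelihood-ratio tests for physical activity (IPAQ MET-min/week) and hip
strength (bilateral mean MS_average, between-limb difference MS_diff); and
muscle-group-specific association models.

## Worked example

```python
from trunkgait.pipeline import PipelineConfig, process_recording
from trunkgait.synthetic import calibrate_default_adult, gen_walk_recording

rec, truth = gen_walk_recording(calibrate_default_adult(seed=1))
row = process_recording(rec, PipelineConfig(strict=True))
```

prints (via the twelve outcome entries of `row`):

```
step_symmetry    VT=+0.836  ML=+0.628  AP=+0.846
stride_symmetry  VT=+0.932  ML=+0.943  AP=+0.934
stability        VT=+1.324  ML=+0.847  AP=+1.147
smoothness       VT=-9.761  ML=-14.762  AP=-12.067
```

Step symmetry near 0.84 and stride symmetry near 0.93 indicate regular,
mildly asymmetric walking (the generator's default attenuates every second
step to 88 %); λ ≈ 1.3 per stride is a typical healthy-adult short-term
divergence rate; the SPARC values are strongly negative because the metric
is computed over the whole 300-stride bout (see `docs/methods.md` on why
whole-bout SPARC magnitudes are larger than windowed ones).

The cohort layer on a synthetic 6-decade × 15-participant cohort:

```python
from trunkgait.stats import ancova_group, fit_age_model
from trunkgait.synthetic import gen_cohort

cohort = gen_cohort(seed=7)
res = fit_age_model(cohort, "stability_VT")
anc = ancova_group(cohort, "stability_VT", bootstrap_B=500, seed=0)
```

```
stability_VT age model: slope=0.0051 (SE 0.0008), p=1.8e-09, adj R2=0.33, RMSE=0.123
ANCOVA age-group: F=9.01 p=7.47e-07 omega2=0.309 CI=(0.177, 0.497)
```

The fitted slope (+0.0051 λ-units/year) recovers the generating model's
+0.0048 within one standard error: stability declines measurably across
adulthood in this cohort.

## Command line

```bash
trunkgait simulate-signal --out walk.csv --seed 1          # synthetic recording
trunkgait process walk.csv --out gait.csv                  # 12 outcomes per file
trunkgait simulate-cohort --out cohort.csv --seed 2        # synthetic cohort table
trunkgait analyze cohort.csv --out results/                # full statistics bundle
trunkgait calibrate --seeds 5                              # default-generator check
```

`process` accepts globs and a JSON config file (`--config`); every output
embeds a hash of the configuration used.

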