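"""Synthetic gait signals and synthetic cohorts with known ground truth.

Two generators form the test bed for the whole pipeline:

* :func:`gen_walk_recording` synthesises a lower-back IMU stream for steady
  walking by harmonic synthesis on a jittered stride-phase clock.  The
  vertical and anteroposterior accelerations are dominated by the step
  harmonic and the mediolateral acceleration by the stride harmonic,
  matching the physiological trunk spectra the gait metrics assume.  Every
  second step can be attenuated (left/right asymmetry), stride times drift
  by a bounded random walk (local instability), and high-frequency power can
  be injected into the angular velocity (reduced smoothness).  Gravity and a
  known sensor tilt are applied last, so the output is a raw sensor-frame
  recording with ground-truth step times attached.

* :func:`gen_cohort` draws participant tables whose gait outcomes follow
  configurable linear/quadratic age models with Gaussian residuals, on a
  six-decade by fifteen-participant design.

Both are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from trunkgait.covariates import MUSCLE_GROUPS
from trunkgait.orientation import tilt_rotation
from trunkgait.signal_io import GAIT_QUALITY_COLUMNS, IMURecording, STANDARD_GRAVITY


@dataclass(frozen=True)
class SignalGenParams:
    """Tunable knobs of the walking-signal generator.

    step_freq : steps per second (typical adult ~1.9 Hz).
    asym_alpha : amplitude scale of every second step, in (0, 1]; 1 = fully
        symmetric.  Lowers step symmetry without touching stride symmetry.
    stride_time_jitter_sd : per-stride increment SD (s) of the bounded
        random walk perturbing stride onsets; raises the Lyapunov exponent.
    noise_sd : additive white accelerometer noise as a fraction of each
        channel's SD.
    gyro_hf_power : 6-12 Hz band-limited power injected into angular
        velocity, as a fraction of each channel's SD; drives SPARC down.
    tilt_sagittal / tilt_frontal : sensor mounting tilt in degrees.
    """

    step_freq: float = 1.9
    duration_s: float = 330.0
    fs: float = 200.0
    asym_alpha: float = 0.9
    stride_time_jitter_sd: float = 0.012
    noise_sd: float = 0.30
    gyro_hf_power: float = 0.20
    tilt_sagittal: float = 5.0
    tilt_frontal: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 4 * self.step_freq:
            raise ValueError("fs must be at least 4x the step frequency")
        if not (0 < self.asym_alpha <= 1):
            raise ValueError("asym_alpha must be in (0, 1]")
        if self.stride_time_jitter_sd < 0 or self.noise_sd < 0 or self.gyro_hf_power < 0:
            raise ValueError("jitter, noise and HF power must be >= 0")


def calibrate_default_adult(**overrides) -> SignalGenParams:
    """The packaged 'realistic adult' parameter set.

    Chosen with scripts/calibrate.py so that the full pipeline, run on
    generator output, lands inside the healthy-adult reference bands for
    step symmetry, stability and smoothness (vertical axis).  Keyword
    overrides return a modified copy.
    """
    base = SignalGenParams(
        step_freq=1.9,
        duration_s=330.0,
        fs=200.0,
        asym_alpha=0.88,
        stride_time_jitter_sd=0.025,
        noise_sd=0.18,
        gyro_hf_power=0.35,
        tilt_sagittal=5.0,
        tilt_frontal=2.0,
    )
    return replace(base, **overrides) if overrides else base


def _stride_onsets(params: SignalGenParams, rng: np.random.Generator) -> np.ndarray:
    """Stride onset times: regular grid + bounded random walk."""
    T = 2.0 / params.step_freq
    n = int(np.floor(params.duration_s / T)) + 1
    sd = params.stride_time_jitter_sd
    if sd > 0:
        bound = min(3.0 * sd, 0.2 * T)
        w = np.empty(n)
        w[0] = 0.0
        for i in range(1, n):
            w[i] = np.clip(w[i - 1] + rng.normal(0.0, sd), -bound, bound)
    else:
        w = np.zeros(n)
    onsets = np.arange(n) * T + w
    onsets[0] = 0.0
    return onsets


def _mid_steps(
    onsets: np.ndarray, params: SignalGenParams, rng: np.random.Generator
) -> np.ndarray:
    """Second-step times within each stride: midpoints + bounded random walk.

    Stride-onset jitter alone would be undone by per-stride time
    normalisation; wandering of the contralateral step *within* the stride
    is what perturbs the normalised waveform stride to stride (step-time
    variability), so the same jitter process also drives the mid-step
    fraction.
    """
    mids = (onsets[:-1] + onsets[1:]) / 2
    sd = params.stride_time_jitter_sd
    if sd > 0:
        T = 2.0 / params.step_freq
        bound = min(3.0 * sd, 0.15 * T)
        w = np.empty(len(mids))
        w[0] = 0.0
        for i in range(1, len(mids)):
            w[i] = np.clip(w[i - 1] + rng.normal(0.0, sd), -bound, bound)
        mids = mids + w
        mids = np.clip(mids, onsets[:-1] + 0.1 * T, onsets[1:] - 0.1 * T)
    return mids


def _phase(t: np.ndarray, onsets: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Continuous stride phase: knots at stride onsets (integer phase) and
    the jittered mid-stride steps (phase i + 1/2)."""
    n_strides = len(onsets) - 1
    knots_t = np.empty(2 * n_strides + 1)
    knots_t[0::2] = onsets
    knots_t[1::2] = mids
    knots_p = np.empty_like(knots_t)
    knots_p[0::2] = np.arange(n_strides + 1)
    knots_p[1::2] = np.arange(n_strides) + 0.5
    return np.interp(t, knots_t, knots_p)


_HP_SOS_CACHE: dict = {}


def _hf_band(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited (6-12 Hz) noise."""
    key = (round(fs, 6),)
    if key not in _HP_SOS_CACHE:
        _HP_SOS_CACHE[key] = butter(4, [6.0 / (fs / 2), 12.0 / (fs / 2)], btype="band", output="sos")
    x = sosfiltfilt(_HP_SOS_CACHE[key], rng.standard_normal(n))
    return x / np.std(x)


def gen_walk_recording(params: SignalGenParams) -> tuple[IMURecording, dict]:
    """Synthesise a raw sensor-frame walking recording.

    Returns the recording plus a ground-truth dict with ``step_times`` (s),
    ``stride_onsets`` (s), the tilt angles and the generating parameters.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    onsets = _stride_onsets(params, rng)
    mids = _mid_steps(onsets, params, rng)
    phi = 2 * np.pi * _phase(t, onsets, mids)  # radians, one stride = 2*pi

    # every-second-step envelope: 1 at stride onset steps, alpha at mid-stride steps
    a = params.asym_alpha
    env = (1 + a) / 2 + (1 - a) / 2 * np.cos(phi)

    # slow stride-to-stride amplitude wander, driven by the same variability
    # knob as the timing jitter (the two co-occur physiologically); it leaves
    # the autocorrelation peaks nearly untouched but feeds trajectory
    # divergence after time normalisation
    n_str = len(onsets) - 1
    sd_amp = 2.0 * params.stride_time_jitter_sd / (2.0 / params.step_freq)
    if sd_amp > 0:
        bound = min(3.0 * sd_amp, 0.35)
        wa = np.empty(n_str)
        wa[0] = 0.0
        for i in range(1, n_str):
            wa[i] = np.clip(wa[i - 1] + rng.normal(0.0, sd_amp), -bound, bound)
        gain = 1.0 + np.interp(phi / (2 * np.pi), np.arange(n_str) + 0.5, wa)
    else:
        gain = np.ones(n)

    # global-frame linear acceleration (m/s^2); step harmonic = 2 cycles/stride.
    # Odd (stride-frequency) harmonics in VT/AP encode residual left/right
    # difference, so they scale away as asym_alpha -> 1 (a perfectly
    # symmetric walker has a purely step-periodic trunk signal there).
    odd = min(1.0, (1.0 - a) / 0.12)
    acc_vt = 1.8 * (env * np.cos(2 * phi) + 0.30 * np.cos(4 * phi + 0.6) + odd * 0.10 * np.cos(phi + 0.3))
    acc_ap = 1.2 * (env * np.cos(2 * phi + 0.0) + 0.25 * np.cos(4 * phi + 1.1) + odd * 0.12 * np.cos(phi + 1.0))
    # ML carries both sway components; the step harmonic dominates so that
    # the step-lag autocorrelation peak is positive (healthy-adult reference
    # cohorts show ML step symmetry ~ 0.6, close to stride symmetry)
    acc_ml = 0.9 * (0.35 * np.cos(phi + 0.5) + env * np.cos(2 * phi + 0.9) + 0.12 * np.cos(3 * phi + 0.2))

    # global-frame angular velocity (rad/s); rotation axes: roll~AP, pitch~ML, yaw~VT
    gyr_pitch = 0.45 * (np.cos(2 * phi + 0.4) + 0.25 * np.cos(4 * phi + 1.3) + 0.10 * np.cos(6 * phi + 0.2))
    gyr_roll = 0.35 * (np.cos(phi + 1.2) + 0.30 * np.cos(2 * phi + 0.1) + 0.12 * np.cos(3 * phi + 0.8))
    gyr_yaw = 0.40 * (np.cos(phi + 2.0) + 0.25 * np.cos(2 * phi + 1.5) + 0.10 * np.cos(4 * phi + 0.9))

    acc_vt, acc_ap, acc_ml = gain * acc_vt, gain * acc_ap, gain * acc_ml
    if params.noise_sd > 0:
        for arr in (acc_vt, acc_ap, acc_ml):
            arr += params.noise_sd * np.std(arr) * rng.standard_normal(n)
    if params.gyro_hf_power > 0:
        for arr in (gyr_pitch, gyr_roll, gyr_yaw):
            arr += params.gyro_hf_power * np.std(arr) * _hf_band(n, fs, rng)
    # small sensor noise floor on the gyro regardless of the HF knob
    for arr in (gyr_pitch, gyr_roll, gyr_yaw):
        arr += 0.01 * rng.standard_normal(n)

    acc_global = np.column_stack([acc_ap, acc_ml, acc_vt + STANDARD_GRAVITY])
    gyro_global = np.column_stack([gyr_roll, gyr_pitch, gyr_yaw])

    R_sg = tilt_rotation(params.tilt_sagittal, params.tilt_frontal)  # sensor-from-global
    acc_sensor = acc_global @ R_sg.T
    gyro_sensor = gyro_global @ R_sg.T

    rec = IMURecording(
        t=t,
        acc=acc_sensor,
        gyro=gyro_sensor,
        fs=fs,
        subject_id=f"synthetic_{params.seed}",
    )
    # ground-truth steps: AP step harmonic peaks at stride onset and mid-stride
    step_times = np.sort(np.concatenate([onsets, mids]))
    step_times = step_times[step_times <= t[-1]]
    truth = {
        "step_times": step_times,
        "stride_onsets": onsets[onsets <= t[-1]],
        "tilt": (params.tilt_sagittal, params.tilt_frontal),
        "params": params,
    }
    return rec, truth


@dataclass(frozen=True)
class OutcomeModel:
    """Generating age model for one outcome: value = intercept + slope*age
    [+ quad*age^2] + Normal(0, resid_sd)."""

    intercept: float
    slope: float
    quad: float | None
    resid_sd: float
    n: int = 90  # complete cases to keep (missingness = 90 - n)


#: Default generating models for the twelve outcomes (healthy-adult
#: reference values for a six-decade cohort).
DEFAULT_OUTCOME_MODELS: dict[str, OutcomeModel] = {
    "step_symmetry_VT": OutcomeModel(0.94, -0.0016, None, 0.07, 89),
    "step_symmetry_ML": OutcomeModel(0.52, -0.0022, None, 0.11, 89),
    "step_symmetry_AP": OutcomeModel(0.79, 0.0045, -0.000063, 0.07, 89),
    "stride_symmetry_VT": OutcomeModel(0.87, -0.0006, None, 0.08, 89),
    "stride_symmetry_ML": OutcomeModel(0.45, -0.0008, None, 0.12, 89),
    "stride_symmetry_AP": OutcomeModel(0.79, -0.0006, None, 0.07, 88),
    "stability_VT": OutcomeModel(1.05, 0.0048, None, 0.12, 88),
    "stability_ML": OutcomeModel(0.99, 0.0036, None, 0.14, 89),
    "stability_AP": OutcomeModel(1.12, 0.0026, None, 0.14, 90),
    "smoothness_VT": OutcomeModel(-1.67, 0.0156, -0.000160, 0.11, 89),
    "smoothness_ML": OutcomeModel(-1.40, -0.0001, None, 0.12, 89),
    "smoothness_AP": OutcomeModel(-1.54, 0.0015, None, 0.18, 90),
}


@dataclass(frozen=True)
class CohortGenParams:
    """Design and generating models of a synthetic cohort.

    decades : inclusive lower bounds of the age decades sampled.
    n_per_decade : participants per decade (ages uniform within decade).
    p_female : marginal probability of gender F.
    bmi_mean / bmi_sd : BMI marginal (kg/m^2), truncated to [16, 40].
    outcome_models : per-outcome generating models (age effects only by
        default; gender/BMI effects are zero).
    strength_effect / met_effect : optional linear effects of the strength
        and MET columns injected into every outcome (0 = none).
    missingness : when True, drop outcomes at random down to each model's n.
    """

    decades: tuple[int, ...] = (20, 30, 40, 50, 60, 70)
    n_per_decade: int = 15
    p_female: float = 54 / 90
    bmi_mean: float = 24.5
    bmi_sd: float = 3.6
    outcome_models: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MODELS))
    strength_effect: float = 0.0
    met_effect: float = 0.0
    missingness: bool = False
    seed: int = 0


#: Rough healthy-adult means (N) for maximal isometric hip strength by group.
_STRENGTH_MEANS = {
    "abductors": 180.0,
    "adductors": 160.0,
    "extensors": 220.0,
    "flexors": 200.0,
    "internal_rotators": 120.0,
    "external_rotators": 110.0,
}


def gen_cohort(params: CohortGenParams | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Ages are uniform within each decade; gender and BMI follow the stated
    marginals; each outcome is its generating age model plus Gaussian
    residual noise.  MET and per-muscle-group strength columns are included
    with mild age trends; their effects on the outcomes are zero unless
    configured otherwise.  Deterministic for a given (params, seed).
    """
    params = params or CohortGenParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    ages = np.concatenate(
        [rng.uniform(d, d + 10, size=params.n_per_decade) for d in params.decades]
    )
    n = len(ages)
    gender = np.where(rng.random(n) < params.p_female, "F", "M")
    bmi = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, size=n), 16.0, 40.0)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": ages,
            "gender": gender,
            "bmi": bmi,
        }
    )

    # physical activity: right-skewed MET-min/week, mild age-independent
    df["MET"] = np.round(rng.lognormal(mean=7.6, sigma=0.7, size=n), 1)

    # hip strength: per-group bilateral mean with a mild age decline and
    # between-limb difference
    for grp, mu in _STRENGTH_MEANS.items():
        base = mu * (1.0 - 0.004 * (ages - 45.0)) + rng.normal(0, 0.12 * mu, size=n)
        base = np.maximum(base, 20.0)
        diff = np.abs(rng.normal(0, 0.06 * mu, size=n))
        df[f"{grp}_ms_average"] = np.round(base, 1)
        df[f"{grp}_ms_diff"] = np.round(diff, 1)
    df["MS_average"] = df[[f"{g}_ms_average" for g in MUSCLE_GROUPS]].mean(axis=1)
    df["MS_diff"] = df[[f"{g}_ms_diff" for g in MUSCLE_GROUPS]].mean(axis=1)

    strength_c = df["MS_average"] - df["MS_average"].mean()
    met_c = df["MET"] - df["MET"].mean()
    for outcome, m in params.outcome_models.items():
        mu_out = m.intercept + m.slope * ages
        if m.quad is not None:
            mu_out = mu_out + m.quad * ages**2
        vals = (
            mu_out
            + params.strength_effect * strength_c
            + params.met_effect * met_c
            + rng.normal(0.0, m.resid_sd, size=n)
        )
        if params.missingness and m.n < n:
            drop = rng.choice(n, size=n - m.n, replace=False)
            vals = np.asarray(vals, dtype=float)
            vals[drop] = np.nan
        df[outcome] = vals

    for col in GAIT_QUALITY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df
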