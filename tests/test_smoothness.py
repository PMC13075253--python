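import numpy as np
import pytest

from trunkgait.errors import SignalError
from trunkgait.orientation import OrientedGait
from trunkgait.smoothness import smoothness_per_axis, sparc

from oracles import trapezoid_spectral_arc

FS = 200.0


def _sine(f=1.0, dur=10.0, amp=1.0):
    t = np.arange(0, dur, 1 / FS)
    return amp * np.sin(2 * np.pi * f * t)


def test_sparc_equals_arc_length_oracle():
    """Value equals an independent point-by-point arc-length summation of
    the same normalised spectrum, to 1e-9."""
    rng = np.random.default_rng(0)
    v = _sine(1.0) + 0.4 * _sine(3.0) + 0.05 * rng.standard_normal(2000)
    assert sparc(v, FS).value == pytest.approx(trapezoid_spectral_arc(v, FS), abs=1e-9)


def test_sparc_amplitude_invariant():
    v = _sine(1.0) + 0.2 * _sine(5.0)
    a = sparc(v, FS).value
    b = sparc(2.0 * v, FS).value
    assert a == pytest.approx(b, abs=1e-9)


def test_sparc_time_shift_invariant():
    """A movement bump shifted within the analysis window (no content
    crossing the edges) leaves the magnitude spectrum, hence SPARC,
    unchanged to machine precision."""
    t = np.arange(0, 10, 1 / FS)

    def bump(center):
        return np.exp(-0.5 * ((t - center) / 0.4) ** 2) * np.sin(2 * np.pi * 1.5 * (t - center))

    a = sparc(bump(4.0), FS).value
    b = sparc(bump(6.0), FS).value
    assert a == pytest.approx(b, abs=1e-9)
    # a periodic window shifted by an integer number of periods is the
    # identical sequence: exact equality
    c1 = sparc(np.sin(2 * np.pi * t), FS).value
    c2 = sparc(np.sin(2 * np.pi * (t + 3.0)), FS).value
    assert c1 == pytest.approx(c2, abs=1e-9)


def test_added_high_frequency_component_more_negative():
    v1 = _sine(1.0)
    v2 = _sine(1.0) + 0.3 * _sine(6.0)
    assert sparc(v2, FS).value < sparc(v1, FS).value


def test_band_power_sweep_never_increases_value():
    """Growing 6 Hz content below fc makes the spectrum arc strictly
    longer (checked on a 5-point amplitude sweep)."""
    vals = [sparc(_sine(1.0) + a * _sine(6.0), FS).value for a in (0.1, 0.2, 0.3, 0.4, 0.5)]
    assert all(b <= a for a, b in zip(vals, vals[1:]))


def test_all_zero_signal_rejected():
    with pytest.raises(SignalError):
        sparc(np.zeros(2000), FS)


def _oriented_from_gyro(yaw, pitch, roll):
    z = np.zeros_like(yaw)
    return OrientedGait(acc_AP=z, acc_VT=z, acc_ML=z, gyro_yaw=yaw,
                        gyro_pitch=pitch, gyro_roll=roll, fs=FS)


def test_identical_axes_give_identical_values():
    v = _sine(1.0) + 0.2 * _sine(4.0)
    out = smoothness_per_axis(_oriented_from_gyro(v, v.copy(), v.copy()))
    assert out["VT"].value == out["ML"].value == out["AP"].value
    assert out["VT"].axis == "yaw->VT"


def test_axis_permutation_permutes_outputs():
    a, b, c = _sine(1.0), _sine(1.5) + 0.3 * _sine(4.5), _sine(0.8) + 0.1 * _sine(7.0)
    out1 = smoothness_per_axis(_oriented_from_gyro(a, b, c))
    out2 = smoothness_per_axis(_oriented_from_gyro(b, c, a))
    assert out2["VT"].value == pytest.approx(out1["ML"].value, abs=1e-12)
    assert out2["ML"].value == pytest.approx(out1["AP"].value, abs=1e-12)
    assert out2["AP"].value == pytest.approx(out1["VT"].value, abs=1e-12)


def test_noise_on_one_axis_only_degrades_that_direction():
    rng = np.random.default_rng(1)
    base = _sine(1.0) + 0.2 * _sine(3.0)
    noisy = base + 0.25 * base.std() * rng.standard_normal(len(base))
    clean = smoothness_per_axis(_oriented_from_gyro(base, base.copy(), base.copy()))
    mixed = smoothness_per_axis(_oriented_from_gyro(base, noisy, base.copy()))
    assert mixed["ML"].value < clean["ML"].value - 0.02
    assert mixed["VT"].value == pytest.approx(clean["VT"].value, abs=0.02)
    assert mixed["AP"].value == pytest.approx(clean["AP"].value, abs=0.02)


def test_per_stride_mode_runs_on_pipeline_output(default_gait):
    oriented, events, _ = default_gait
    whole = smoothness_per_axis(oriented, events, mode="whole")
    windowed = smoothness_per_axis(oriented, events, mode="per_stride")
    for ax in ("VT", "ML", "AP"):
        assert whole[ax].value < -1.0
        assert windowed[ax].value < -1.0
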