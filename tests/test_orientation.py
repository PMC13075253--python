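import numpy as np
import pytest

from trunkgait.errors import SignalError
from trunkgait.orientation import TiltCorrection, estimate_tilt, reorient, tilt_rotation
from trunkgait.signal_io import IMURecording, STANDARD_GRAVITY

G = STANDARD_GRAVITY


def _gravity_recording(sagittal=0.0, frontal=0.0, n=6000, fs=200.0, walk_amp=0.0, seed=0):
    """Gravity (+ optional zero-mean walking oscillation) seen by a sensor
    tilted by the given angles."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    acc_global = np.zeros((n, 3))
    acc_global[:, 2] = G
    if walk_amp:
        acc_global[:, 0] += walk_amp * np.sin(2 * np.pi * 1.9 * t)
        acc_global[:, 1] += 0.5 * walk_amp * np.sin(2 * np.pi * 0.95 * t + 1.0)
        acc_global[:, 2] += walk_amp * np.cos(2 * np.pi * 1.9 * t + 0.3)
    R_sg = tilt_rotation(sagittal, frontal)
    return IMURecording(t=t, acc=acc_global @ R_sg.T, gyro=rng.normal(0, 0.1, (n, 3)), fs=fs)


def test_pure_gravity_gives_identity():
    tilt = estimate_tilt(_gravity_recording())
    assert abs(tilt.sagittal_tilt) < 1e-6
    assert abs(tilt.frontal_tilt) < 1e-6
    np.testing.assert_allclose(tilt.rotation, np.eye(3), atol=1e-9)


@pytest.mark.parametrize("sag,front", [(10.0, 0.0), (10.0, 5.0), (-7.0, 3.0)])
def test_known_tilt_recovered(sag, front):
    tilt = estimate_tilt(_gravity_recording(sag, front))
    assert tilt.sagittal_tilt == pytest.approx(sag, abs=0.1)
    assert tilt.frontal_tilt == pytest.approx(front, abs=0.1)


def test_tilt_estimate_robust_to_walking_oscillation():
    """Zero-mean AP/ML/VT oscillation superimposed on tilted gravity must
    not bias the estimate by more than half a degree."""
    tilt = estimate_tilt(_gravity_recording(10.0, 5.0, walk_amp=2.0))
    assert tilt.sagittal_tilt == pytest.approx(10.0, abs=0.5)
    assert tilt.frontal_tilt == pytest.approx(5.0, abs=0.5)


def test_rotation_invariants():
    tilt = estimate_tilt(_gravity_recording(12.0, -4.0))
    R = tilt.rotation
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_no_gravity_reference_error():
    rec = _gravity_recording()
    rec = IMURecording(t=rec.t, acc=rec.acc * 0.01, gyro=rec.gyro, fs=rec.fs)
    with pytest.raises(SignalError):
        estimate_tilt(rec)


def test_reorient_inverts_known_tilt_exactly():
    """Rotating a global-frame signal into the sensor frame and reorienting
    with the matching correction recovers it to 1e-9."""
    rng = np.random.default_rng(3)
    n, fs = 4000, 200.0
    acc_global = rng.normal(0, 1.5, (n, 3))
    acc_global[:, 2] += G
    gyro_global = rng.normal(0, 0.4, (n, 3))
    R_sg = tilt_rotation(8.0, -3.0)
    rec = IMURecording(
        t=np.arange(n) / fs, acc=acc_global @ R_sg.T, gyro=gyro_global @ R_sg.T, fs=fs
    )
    tilt = TiltCorrection(
        rotation=R_sg.T, sagittal_tilt=8.0, frontal_tilt=-3.0, gravity_mag=G
    )
    out = reorient(rec, tilt)
    np.testing.assert_allclose(out.acc_AP, acc_global[:, 0], atol=1e-9)
    np.testing.assert_allclose(out.acc_ML, acc_global[:, 1], atol=1e-9)
    np.testing.assert_allclose(out.acc_VT, acc_global[:, 2] - G, atol=1e-9)
    np.testing.assert_allclose(out.gyro_roll, gyro_global[:, 0], atol=1e-9)
    np.testing.assert_allclose(out.gyro_pitch, gyro_global[:, 1], atol=1e-9)
    np.testing.assert_allclose(out.gyro_yaw, gyro_global[:, 2], atol=1e-9)


def test_rotation_preserves_signal_energy():
    rec = _gravity_recording(9.0, 4.0, walk_amp=2.0)
    tilt = estimate_tilt(rec)
    out = reorient(rec, tilt)
    acc_out = np.column_stack([out.acc_AP, out.acc_ML, out.acc_VT + tilt.gravity_mag])
    assert np.sum(acc_out**2) == pytest.approx(np.sum(rec.acc**2), rel=1e-9)


def test_reoriented_vt_mean_near_zero(default_gait):
    oriented, _, _ = default_gait
    assert abs(np.mean(oriented.acc_VT)) < 0.05
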