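"""Tilt correction: rotate raw sensor axes into the global AP/VT/ML frame.

The sensor is worn at the lower back with nominal axis labels
(x ~ anteroposterior, y ~ mediolateral, z ~ vertical) but is never perfectly
aligned with gravity.  Following the trunk-accelerometry tradition, the
gravitational component of the acceleration signal (low-pass filtered) gives
the sensor's attitude, and two successive rotations — about the mediolateral
axis (sagittal tilt) then about the anteroposterior axis (frontal tilt) —
align the vertical axis with gravity.  Residual yaw about the vertical is not
observable from gravity alone and is left uncorrected (known limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from trunkgait.errors import SignalError
from trunkgait.signal_io import IMURecording, STANDARD_GRAVITY


@dataclass(frozen=True)
class TiltCorrection:
    """Sensor-to-global rotation estimated from the gravity vector.

    ``rotation`` maps sensor-frame 3-vectors (x, y, z) into the global frame
    ordered (AP, ML, VT).  ``gravity_mag`` is the magnitude of the mean
    acceleration over the estimation window, subtracted from VT on reorient.
    """

    rotation: np.ndarray
    sagittal_tilt: float  # degrees, rotation about the ML axis
    frontal_tilt: float   # degrees, rotation about the AP axis
    gravity_mag: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)


@dataclass
class OrientedGait:
    """Gravity-referenced gait signals in the global AP/VT/ML frame.

    Linear acceleration per axis in m/s^2 with gravity removed from VT;
    angular velocity relabelled by the axis rotated about:
    yaw -> VT, pitch -> ML, roll -> AP.
    """

    acc_AP: np.ndarray
    acc_VT: np.ndarray
    acc_ML: np.ndarray
    gyro_yaw: np.ndarray
    gyro_pitch: np.ndarray
    gyro_roll: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.acc_AP)
        for name in ("acc_VT", "acc_ML", "gyro_yaw", "gyro_pitch", "gyro_roll"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.acc_AP)

    def acc_axis(self, axis: str) -> np.ndarray:
        return {"AP": self.acc_AP, "VT": self.acc_VT, "ML": self.acc_ML}[axis]

    def gyro_axis(self, axis: str) -> np.ndarray:
        # rotational axis mapped to the direction it rotates about
        return {"VT": self.gyro_yaw, "ML": self.gyro_pitch, "AP": self.gyro_roll}[axis]

    def sliced(self, stop: int) -> "OrientedGait":
        return OrientedGait(
            acc_AP=self.acc_AP[:stop],
            acc_VT=self.acc_VT[:stop],
            acc_ML=self.acc_ML[:stop],
            gyro_yaw=self.gyro_yaw[:stop],
            gyro_pitch=self.gyro_pitch[:stop],
            gyro_roll=self.gyro_roll[:stop],
            fs=self.fs,
            subject_id=self.subject_id,
        )


def _rot_y(theta: float) -> np.ndarray:
    """Rotation about the ML (y) axis by theta radians."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(phi: float) -> np.ndarray:
    """Rotation about the AP (x) axis by phi radians."""
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def tilt_rotation(sagittal_deg: float, frontal_deg: float) -> np.ndarray:
    """Sensor-from-global rotation for a known tilt (used by the simulator).

    A sensor tilted by ``sagittal_deg`` about ML then ``frontal_deg`` about AP
    sees global vectors through the transpose of the correction returned by
    :func:`estimate_tilt`.
    """
    theta = np.deg2rad(sagittal_deg)
    phi = np.deg2rad(frontal_deg)
    # correction = rot_x(phi) @ rot_y(-theta); sensor-from-global is its inverse
    return (_rot_x(phi) @ _rot_y(-theta)).T


def estimate_tilt(
    recording: IMURecording,
    window_s: float = 30.0,
    lowpass_hz: float = 0.1,
) -> TiltCorrection:
    """Estimate sensor tilt from the gravitational acceleration component.

    The raw channels are low-pass filtered (4th-order zero-phase Butterworth
    at ``lowpass_hz``) and averaged over the first ``window_s`` seconds; the
    resulting mean vector is the gravity direction in the sensor frame.  Two
    rotations (sagittal, then frontal) align it with the vertical axis.

    Raises :class:`SignalError` when the mean acceleration magnitude is below
    0.5 g — no usable gravity reference.
    """
    fs = recording.fs
    n = recording.n_samples
    n_win = min(int(round(window_s * fs)), n)
    if n_win / fs < 10.0:
        raise SignalError("tilt estimation window must cover at least 10 s")

    # filter the whole recording, then average an interior window: the
    # zero-phase low-pass has edge transients on the scale of 1/lowpass_hz
    # that would bias a short leading window
    nyq = fs / 2.0
    sos = butter(4, lowpass_hz / nyq, btype="low", output="sos")
    grav = sosfiltfilt(sos, recording.acc, axis=0)
    margin = int(min(2.0 / lowpass_hz * fs, max(0, (n - n_win) // 2)))
    g_vec = grav[margin : margin + n_win].mean(axis=0)
    g_mag = float(np.linalg.norm(g_vec))
    if g_mag < 0.5 * STANDARD_GRAVITY:
        raise SignalError(
            f"no gravity reference: mean acceleration {g_mag:.2f} m/s^2 < 0.5 g"
        )

    gx, gy, gz = g_vec
    # sagittal: rotate about y so the x (AP) component of gravity vanishes
    theta = np.arctan2(gx, gz)
    v = _rot_y(-theta) @ g_vec
    # frontal: rotate about x so the y (ML) component vanishes
    phi = np.arctan2(v[1], v[2])
    R = _rot_x(phi) @ _rot_y(-theta)

    check = R @ g_vec
    if abs(check[2] - g_mag) > 1e-6 * g_mag:
        raise SignalError("tilt correction failed to align gravity with VT")

    return TiltCorrection(
        rotation=R,
        sagittal_tilt=float(np.rad2deg(theta)),
        frontal_tilt=float(np.rad2deg(phi)),
        gravity_mag=g_mag,
    )


def reorient(recording: IMURecording, tilt: TiltCorrection) -> OrientedGait:
    """Apply a tilt correction sample-wise and remove gravity from VT.

    Rotation is applied to both acceleration and angular velocity; the
    gravity magnitude estimated over the tilt window is subtracted from the
    vertical acceleration.  Gyro channels are relabelled by rotation axis:
    yaw (about VT), pitch (about ML), roll (about AP).
    """
    acc_g = recording.acc @ tilt.rotation.T
    gyro_g = recording.gyro @ tilt.rotation.T
    return OrientedGait(
        acc_AP=acc_g[:, 0],
        acc_ML=acc_g[:, 1],
        acc_VT=acc_g[:, 2] - tilt.gravity_mag,
        gyro_roll=gyro_g[:, 0],
        gyro_pitch=gyro_g[:, 1],
        gyro_yaw=gyro_g[:, 2],
        fs=recording.fs,
        subject_id=recording.subject_id,
    )
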