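"""Reading and writing IMU recordings and tabular cohort data.

File conventions: header-named CSV, UTF-8, "." decimal.  A recording file
carries seven columns — a time column plus three acceleration and three
angular-velocity channels.  Units are declared through :class:`UnitConfig`
(acceleration in ``m/s2`` or ``g``); everything is converted to SI on load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trunkgait.errors import SchemaError, UnitError

logger = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2

ACC_COLUMNS = ("acc_x", "acc_y", "acc_z")
GYRO_COLUMNS = ("gyro_x", "gyro_y", "gyro_z")
TIME_COLUMN = "t"

#: The twelve per-participant gait-quality outcomes, axis-suffixed.
GAIT_QUALITY_COLUMNS = tuple(
    f"{metric}_{axis}"
    for metric in ("step_symmetry", "stride_symmetry", "stability", "smoothness")
    for axis in ("VT", "ML", "AP")
)


@dataclass(frozen=True)
class UnitConfig:
    """Declared units and sampling rate of a recording file.

    acc_unit
        ``"m/s2"`` (default) or ``"g"``; values in g are multiplied by
        standard gravity on load.
    gyro_unit
        ``"rad/s"`` (default) or ``"deg/s"``.
    fs
        Declared sampling rate in Hz; cross-checked against the median
        time step of the file (>5 % deviation is an error).
    """

    acc_unit: str = "m/s2"
    gyro_unit: str = "rad/s"
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.acc_unit not in ("m/s2", "g"):
            raise UnitError(f"unknown acceleration unit {self.acc_unit!r}")
        if self.gyro_unit not in ("rad/s", "deg/s"):
            raise UnitError(f"unknown angular-velocity unit {self.gyro_unit!r}")
        if self.fs <= 0:
            raise UnitError("declared sampling rate must be positive")


@dataclass
class IMURecording:
    """A synchronized 6-axis sensor stream.

    t : seconds, monotone; acc : (n, 3) m/s^2; gyro : (n, 3) rad/s.
    Sensor-frame axis order is (x, y, z) with nominal mounting
    x ~ anteroposterior, y ~ mediolateral, z ~ vertical.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise SchemaError("recording needs at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise SchemaError("acc and gyro must be (n, 3) matching t")
        if self.fs <= 0:
            raise UnitError("fs must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise SchemaError("time vector must be strictly increasing")
        if abs(np.median(dt) * self.fs - 1.0) > 0.01:
            raise UnitError(
                f"time spacing (median dt {np.median(dt):.6g} s) inconsistent "
                f"with fs={self.fs} Hz beyond 1%"
            )
        if np.isnan(self.acc).any() or np.isnan(self.gyro).any():
            raise SchemaError("NaN present after load")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


def read_recording(path: str | Path, unit_config: UnitConfig | None = None) -> IMURecording:
    """Load a delimited-text recording, converting to SI units.

    The file must carry columns ``t, acc_x, acc_y, acc_z, gyro_x, gyro_y,
    gyro_z``.  Rows containing NaN are dropped with a logged count (>1 %
    dropped emits a warning).  A JSON sidecar ``<path>.json``, if present,
    supplies the unit configuration when none is passed explicitly.
    """
    path = Path(path)
    if unit_config is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            unit_config = UnitConfig(**{k: meta[k] for k in ("acc_unit", "gyro_unit", "fs") if k in meta})
        else:
            unit_config = UnitConfig()

    df = pd.read_csv(path)
    required = (TIME_COLUMN,) + ACC_COLUMNS + GYRO_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    n_raw = len(df)
    df = df.dropna(subset=list(required))
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("%s: dropped %d row(s) containing NaN", path, n_dropped)
        if n_dropped > 0.01 * n_raw:
            logger.warning("%s: %.1f%% of rows dropped for NaN", path, 100 * n_dropped / n_raw)

    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: fewer than 2 valid samples")
    fs_inferred = 1.0 / float(np.median(np.diff(t)))
    if abs(fs_inferred - unit_config.fs) > 0.05 * unit_config.fs:
        raise UnitError(
            f"{path}: inferred sampling rate {fs_inferred:.1f} Hz deviates >5% "
            f"from declared {unit_config.fs} Hz"
        )

    acc = df[list(ACC_COLUMNS)].to_numpy(dtype=float)
    gyro = df[list(GYRO_COLUMNS)].to_numpy(dtype=float)
    if unit_config.acc_unit == "g":
        acc = acc * STANDARD_GRAVITY
    if unit_config.gyro_unit == "deg/s":
        gyro = np.deg2rad(gyro)

    return IMURecording(t=t, acc=acc, gyro=gyro, fs=unit_config.fs, subject_id=path.stem)


def write_recording(rec: IMURecording, path: str | Path, sidecar: bool = True) -> None:
    """Write a recording as CSV (SI units) with an optional JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({TIME_COLUMN: rec.t})
    for i, c in enumerate(ACC_COLUMNS):
        df[c] = rec.acc[:, i]
    for i, c in enumerate(GYRO_COLUMNS):
        df[c] = rec.gyro[:, i]
    df.to_csv(path, index=False, float_format="%.10g")
    if sidecar:
        meta = {"acc_unit": "m/s2", "gyro_unit": "rad/s", "fs": rec.fs, "subject_id": rec.subject_id}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def write_gait_quality(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-participant gait-quality rows as CSV.

    Round-trip through :func:`read_gait_quality` preserves values to 1e-9.
    An empty row list yields a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(rows, columns=["subject_id", *GAIT_QUALITY_COLUMNS] if not rows else None)
    for col in GAIT_QUALITY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    lead = [c for c in df.columns if c not in GAIT_QUALITY_COLUMNS]
    df = df[lead + list(GAIT_QUALITY_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.12g")


def read_gait_quality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GAIT_QUALITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing outcome columns {missing}")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a cohort table (one row per participant) and validate invariants."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate subject_id values")
    if "age" in df.columns:
        bad = df[(df["age"] < 18) | (df["age"] > 100)]
        if len(bad):
            raise SchemaError(f"{path}: {len(bad)} age value(s) outside [18, 100]")
    return df
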