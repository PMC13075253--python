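"""Step detection on the anteroposterior acceleration, stride building, and
fixed-count truncation.

A single lower-back sensor cannot tell left from right: strides are defined
by step parity from the first detected step.  All downstream symmetry metrics
are parity-invariant, so the arbitrary parity choice is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, periodogram, sosfiltfilt

from trunkgait.errors import NoLocomotionError, SignalError, TruncationError
from trunkgait.orientation import OrientedGait


@dataclass
class GaitEvents:
    """Detected step/stride events with QC flags.

    step_idx : ascending sample indices of step events.
    stride_idx : every second step starting from the first (stride onsets).
    mean_step_s / mean_stride_s : median inter-event intervals in seconds.
    """

    step_idx: np.ndarray
    stride_idx: np.ndarray
    mean_step_s: float
    mean_stride_s: float
    fs: float
    qc_flags: list[str] = field(default_factory=list)
    #: optional sub-sample-refined peak positions (float samples), aligned
    #: with step_idx; used for stride resampling where available
    step_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.step_idx = np.asarray(self.step_idx, dtype=int)
        self.stride_idx = np.asarray(self.stride_idx, dtype=int)
        if np.any(np.diff(self.step_idx) <= 0):
            raise ValueError("step indices must be strictly increasing")
        if self.step_pos is not None:
            self.step_pos = np.asarray(self.step_pos, dtype=float)
            if self.step_pos.shape != self.step_idx.shape:
                raise ValueError("step_pos must align with step_idx")

    @property
    def stride_pos(self) -> np.ndarray:
        """Stride onsets in float samples (sub-sample refined when present)."""
        if self.step_pos is not None:
            return self.step_pos[::2]
        return self.stride_idx.astype(float)

    @property
    def n_steps(self) -> int:
        return len(self.step_idx)

    @property
    def n_strides(self) -> int:
        """Number of complete strides (pairs of consecutive steps)."""
        return (len(self.step_idx) - 1) // 2


DEFAULT_F_BAND = (1.0, 3.0)


def dominant_step_frequency(ap: np.ndarray, fs: float, f_band: tuple[float, float] = DEFAULT_F_BAND) -> float:
    """Dominant step frequency from the AP power spectrum within f_band (Hz)."""
    x = ap - np.mean(ap)
    if np.std(x) == 0:
        raise NoLocomotionError("no locomotion detected: constant AP signal")
    freqs, pxx = periodogram(x, fs=fs)
    mask = (freqs >= f_band[0]) & (freqs <= f_band[1])
    if not mask.any() or np.max(pxx[mask]) <= 0:
        raise NoLocomotionError("no locomotion detected: empty locomotor band")
    band_peak = np.max(pxx[mask])
    # require the locomotor peak to stand clear of the broadband level
    if band_peak < 5.0 * np.median(pxx[freqs > 0]):
        raise NoLocomotionError("no locomotion detected: no spectral peak in 1-3 Hz")
    return float(freqs[mask][np.argmax(pxx[mask])])


def detect_steps(
    oriented: OrientedGait,
    prominence_k: float = 0.3,
    f_band: tuple[float, float] = DEFAULT_F_BAND,
    positive_peaks: bool = True,
    min_steps: int = 20,
) -> GaitEvents:
    """Detect step events as peaks of the AP acceleration.

    The dominant step frequency f_step is estimated from the AP power
    spectrum in ``f_band``; peaks are then located with a minimum inter-peak
    distance of 0.5/f_step and prominence ``prominence_k * SD(AP)``.
    A QC flag records the fraction of inter-step intervals deviating more
    than 40 % from the median interval.
    """
    ap = oriented.acc_AP
    fs = oriented.fs
    if len(ap) / fs < 30.0:
        raise SignalError("step detection needs at least 30 s of signal")

    f_step = dominant_step_frequency(ap, fs, f_band)
    # zero-phase low-pass above the step band so broadband noise cannot
    # displace or fabricate peaks; cutoff leaves the first harmonics intact
    cutoff = min(2.5 * f_step, 0.45 * fs)
    sos = butter(4, cutoff / (fs / 2), btype="low", output="sos")
    smooth = sosfiltfilt(sos, ap)
    signal = smooth if positive_peaks else -smooth
    min_dist = max(1, int(round(0.5 * fs / f_step)))
    prominence = prominence_k * float(np.std(smooth))
    peaks, _ = find_peaks(signal, distance=min_dist, prominence=prominence)
    if len(peaks) < min_steps:
        raise SignalError(f"recording too short: only {len(peaks)} steps detected")

    # sub-sample refinement: parabolic vertex through the peak and its
    # neighbours, so stride boundaries are not quantised to the sample grid
    pos = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(signal) - 1)
    y0 = signal[peaks[inner] - 1]
    y1 = signal[peaks[inner]]
    y2 = signal[peaks[inner] + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    pos[inner] += np.clip(shift, -0.5, 0.5)

    qc_flags: list[str] = []
    intervals = np.diff(peaks) / fs
    med = np.median(intervals)
    frac_irregular = float(np.mean(np.abs(intervals - med) > 0.4 * med))
    qc_flags.append(f"irregular_interval_fraction={frac_irregular:.3f}")
    if frac_irregular > 0.05:
        qc_flags.append("IRREGULAR_TIMING")

    events = GaitEvents(
        step_idx=peaks,
        stride_idx=peaks[::2],
        mean_step_s=float(med),
        mean_stride_s=2.0 * float(med),
        fs=fs,
        qc_flags=qc_flags,
        step_pos=pos,
    )
    return build_strides(events)


def build_strides(events: GaitEvents) -> GaitEvents:
    """Derive stride onsets (every second step) and median interval stats."""
    steps = events.step_idx
    if len(steps) < 2:
        raise SignalError("need at least 2 steps to build strides")
    strides = steps[::2]
    step_s = float(np.median(np.diff(steps))) / events.fs
    if len(strides) >= 2:
        stride_s = float(np.median(np.diff(strides))) / events.fs
    else:
        stride_s = 2.0 * step_s
    return GaitEvents(
        step_idx=steps,
        stride_idx=strides,
        mean_step_s=step_s,
        mean_stride_s=stride_s,
        fs=events.fs,
        qc_flags=list(events.qc_flags),
        step_pos=events.step_pos,
    )


def truncate_strides(
    events: GaitEvents,
    oriented: OrientedGait,
    n_strides: int = 300,
) -> tuple[GaitEvents, OrientedGait]:
    """Cut signal and events at the end of stride ``n_strides``.

    Every recording is reduced to the same stride count so that symmetry and
    stability estimates are comparable across participants.  A shortfall is a
    hard error naming how many strides are missing.
    """
    available = events.n_strides
    if available < n_strides:
        raise TruncationError(
            f"recording has {available} strides, {n_strides} required "
            f"({n_strides - available} short)"
        )
    # stride i spans step 2i .. 2i+2; the end of stride n_strides-1 is step 2*n_strides
    end_step = int(events.step_idx[2 * n_strides])
    keep = events.step_idx[: 2 * n_strides + 1]
    truncated = GaitEvents(
        step_idx=keep,
        stride_idx=keep[::2],
        mean_step_s=events.mean_step_s,
        mean_stride_s=events.mean_stride_s,
        fs=events.fs,
        qc_flags=list(events.qc_flags),
        step_pos=None if events.step_pos is None else events.step_pos[: 2 * n_strides + 1],
    )
    return build_strides(truncated), oriented.sliced(end_step + 1)
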