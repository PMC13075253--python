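"""Movement smoothness of trunk rotation via the spectral arc length (SPARC).

SPARC is the negative arc length of the normalised magnitude spectrum of a
movement signal over a normalised frequency axis: a smooth, nearly
single-frequency rotation has a compact spectrum and a value close to the
lower bound of -1, while broadband or intermittent motion stretches the
spectrum and pushes the value further negative.  Here it is applied to the
trunk angular-velocity channels during walking; the rotational axes map onto
movement directions by the axis rotated about: yaw -> VT, pitch -> ML,
roll -> AP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trunkgait.errors import SignalError
from trunkgait.events import GaitEvents
from trunkgait.orientation import OrientedGait


@dataclass
class SparcResult:
    value: float          # unitless, < 0; closer to zero = smoother
    fc: float             # Hz, upper frequency limit of the arc
    amp_threshold: float  # adaptive-cutoff fraction of the peak magnitude
    axis: str = ""        # e.g. "yaw->VT"


def sparc(
    v: np.ndarray,
    fs: float,
    fc: float = 10.0,
    amp_threshold: float = 0.05,
    pad_level: int = 4,
) -> SparcResult:
    """Spectral arc length of one angular-velocity channel.

    The magnitude spectrum is computed on a zero-padded FFT (next power of
    two >= 2**pad_level * N), normalised by its maximum, restricted to
    [0, fc], and adaptively cut at the highest frequency where the
    normalised magnitude still reaches ``amp_threshold``.  The value is the
    negative Euclidean arc length of the spectrum over the
    cutoff-normalised frequency axis; it is invariant to amplitude scaling
    and to time shifts of the input.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2 * fs:
        raise SignalError("SPARC needs at least 2 s of signal")
    if np.all(v == v[0]) and v[0] == 0:
        raise SignalError("SPARC undefined for an all-zero signal")

    nfft = int(2 ** np.ceil(np.log2(len(v)) + pad_level))
    f = np.arange(nfft) * (fs / nfft)
    Mf = np.abs(np.fft.fft(v, nfft))
    Mf = Mf / np.max(Mf)

    sel = f <= fc
    f_sel, m_sel = f[sel], Mf[sel]
    above = np.nonzero(m_sel >= amp_threshold)[0]
    if len(above) == 0:
        raise SignalError("no spectral content above the amplitude threshold")
    lo, hi = above[0], above[-1]
    f_cut, m_cut = f_sel[lo : hi + 1], m_sel[lo : hi + 1]

    span = f_cut[-1] - f_cut[0]
    if span <= 0:
        raise SignalError("degenerate spectrum: single frequency bin above threshold")
    arc = np.sum(np.sqrt((np.diff(f_cut) / span) ** 2 + np.diff(m_cut) ** 2))
    return SparcResult(value=-float(arc), fc=fc, amp_threshold=amp_threshold)


def smoothness_per_axis(
    oriented: OrientedGait,
    events: GaitEvents | None = None,
    fc: float = 10.0,
    amp_threshold: float = 0.05,
    mode: str = "whole",
) -> dict[str, SparcResult]:
    """SPARC of the yaw, pitch and roll channels over the truncated bout.

    ``mode="whole"`` (default) computes one value per axis over the full
    series; ``mode="per_stride"`` averages per-stride values (requires
    events).  Outputs are keyed by direction with the rotational-axis
    mapping recorded in each result.
    """
    mapping = {"VT": ("gyro_yaw", "yaw->VT"), "ML": ("gyro_pitch", "pitch->ML"), "AP": ("gyro_roll", "roll->AP")}
    out: dict[str, SparcResult] = {}
    for direction, (chan, tag) in mapping.items():
        sig = getattr(oriented, chan)
        if mode == "whole":
            res = sparc(sig, oriented.fs, fc, amp_threshold)
        elif mode == "per_stride":
            if events is None:
                raise ValueError("per_stride mode requires gait events")
            # strides are grouped into consecutive windows of >= 2 s so each
            # window satisfies the SPARC minimum length
            vals = []
            onsets = events.stride_idx
            start = 0
            for i in range(1, len(onsets)):
                if (onsets[i] - onsets[start]) >= 2 * oriented.fs:
                    seg = sig[int(onsets[start]) : int(onsets[i]) + 1]
                    vals.append(sparc(seg, oriented.fs, fc, amp_threshold).value)
                    start = i
            if not vals:
                raise SignalError("no stride window long enough for per-stride SPARC")
            res = SparcResult(value=float(np.mean(vals)), fc=fc, amp_threshold=amp_threshold)
        else:
            raise ValueError(f"unknown SPARC mode {mode!r}")
        res.axis = tag
        out[direction] = res
    return out
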