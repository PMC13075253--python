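"""Step and stride symmetry from the unbiased autocorrelation of trunk
acceleration.

The autocorrelation coefficient at the mean step lag (Ad1) measures how
similar consecutive steps are; at the mean stride lag (Ad2) how similar
consecutive strides are.  Both equal 1 for perfectly regular gait.  Because
they compare the signal with itself shifted by one step (or stride), they do
not require left/right labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, fftconvolve

from trunkgait.errors import SignalError
from trunkgait.events import GaitEvents
from trunkgait.orientation import OrientedGait


@dataclass
class AutocorrResult:
    """Unbiased autocorrelation with the step/stride regularity peaks.

    ``coeff[m] = [1/(N-m)] sum_i x(i) x(i+m)``, normalised by coeff[0];
    ``ad1``/``ad2`` are the dominant peaks near the step/stride lag (NaN when
    no local maximum exists in the search window).
    """

    lags: np.ndarray
    coeff: np.ndarray
    ad1: float = np.nan
    ad2: float = np.nan
    lag1_s: float = np.nan
    lag2_s: float = np.nan
    flags: list[str] = field(default_factory=list)


def unbiased_autocorrelation(x: np.ndarray, max_lag: int) -> AutocorrResult:
    """Unbiased (lag-corrected) autocorrelation of a mean-centred series.

    The raw sum at lag m is divided by N-m so that long lags are not
    attenuated by the shrinking overlap, then normalised by the lag-0 value.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    if max_lag >= N // 2:
        raise ValueError(f"max_lag {max_lag} must be < N/2 = {N // 2}")
    xc = x - x.mean()
    if np.all(xc == 0):
        raise SignalError("autocorrelation undefined for zero-variance signal")
    # FFT-based raw autocovariance sums for lags 0..max_lag
    raw = fftconvolve(xc, xc[::-1], mode="full")[N - 1 : N + max_lag]
    counts = N - np.arange(max_lag + 1)
    a = raw / counts
    coeff = a / a[0]
    coeff[0] = 1.0  # exact by definition
    return AutocorrResult(lags=np.arange(max_lag + 1), coeff=coeff)


def _dominant_peak(coeff: np.ndarray, center: int, window_frac: float) -> tuple[float, int] | None:
    """Highest local maximum within +-window_frac of ``center``; ties -> smallest lag."""
    lo = max(1, int(np.floor(center * (1 - window_frac))))
    hi = min(len(coeff) - 2, int(np.ceil(center * (1 + window_frac))))
    if hi < lo:
        return None
    seg = coeff[lo : hi + 1]
    local_max = argrelextrema(coeff[lo - 1 : hi + 2], np.greater_equal, order=1)[0]
    local_max = [m + lo - 1 for m in local_max if lo <= m + lo - 1 <= hi]
    # strictness: exclude flat plateaus that are not genuine maxima
    cands = [
        m for m in local_max
        if coeff[m] >= coeff[m - 1] and coeff[m] >= coeff[m + 1]
        and (coeff[m] > coeff[m - 1] or coeff[m] > coeff[m + 1])
    ]
    if not cands:
        return None
    best_val = max(coeff[m] for m in cands)
    best_lag = min(m for m in cands if coeff[m] == best_val)
    return float(coeff[best_lag]), int(best_lag)


def step_stride_symmetry(
    axis_signal: np.ndarray,
    events: GaitEvents,
    window_frac: float = 0.25,
    max_lag_strides: float = 2.5,
) -> AutocorrResult:
    """Step (Ad1) and stride (Ad2) symmetry of one acceleration axis.

    The dominant autocorrelation peak is searched within +-``window_frac``
    of the event-derived mean step and stride lags.  A window with no local
    maximum leaves the corresponding coefficient NaN and records a flag —
    that participant's outcome is treated as missing downstream.
    """
    fs = events.fs
    step_lag = int(round(events.mean_step_s * fs))
    stride_lag = int(round(events.mean_stride_s * fs))
    max_lag = min(int(max_lag_strides * stride_lag), len(axis_signal) // 2 - 1)
    res = unbiased_autocorrelation(axis_signal, max_lag)

    p1 = _dominant_peak(res.coeff, step_lag, window_frac)
    p2 = _dominant_peak(res.coeff, stride_lag, window_frac)
    if p1 is not None:
        res.ad1, lag1 = p1
        res.lag1_s = lag1 / fs
    else:
        res.flags.append("no_step_peak")
    if p2 is not None:
        res.ad2, lag2 = p2
        res.lag2_s = lag2 / fs
    else:
        res.flags.append("no_stride_peak")
    return res


def symmetry_per_axis(
    oriented: OrientedGait,
    events: GaitEvents,
    window_frac: float = 0.25,
) -> dict[str, AutocorrResult]:
    """Ad1/Ad2 for the VT, ML and AP acceleration axes independently."""
    return {
        axis: step_stride_symmetry(oriented.acc_axis(axis), events, window_frac)
        for axis in ("VT", "ML", "AP")
    }
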