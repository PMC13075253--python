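"""Local dynamic stability: maximum Lyapunov exponent of trunk acceleration.

The short-term maximum Lyapunov exponent quantifies how quickly nearby
trajectories of the gait dynamics diverge under the small natural
perturbations of walking: larger exponents mean lower local stability.
Estimation follows the nearest-neighbour divergence-curve approach suited to
short, noisy experimental series: the scalar signal is time-normalised to a
fixed number of samples per stride, delay-embedded, and for every point the
mean log distance to its nearest (temporally separated) neighbour is tracked
forward in time; the exponent is the initial slope of that divergence curve,
expressed per stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from trunkgait.errors import SignalError
from trunkgait.events import GaitEvents


@dataclass
class EmbeddingSpec:
    """State-space reconstruction parameters.

    dim : embedding dimension (>= 2); delay : embedding delay in samples;
    n_samples_per_stride : the time-normalisation grid, which also sets the
    Theiler window (one stride) and the unit of the exponent (per stride).
    """

    dim: int
    delay: int
    n_samples_per_stride: int = 100
    method_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.delay < 1:
            raise ValueError("embedding delay must be >= 1")


@dataclass
class DivergenceCurve:
    """Mean log divergence of nearest-neighbour pairs versus time.

    time : strides; mean_log_divergence : ln(distance); lambda_max : the
    least-squares slope over ``fit_range`` (per stride).
    """

    time: np.ndarray
    mean_log_divergence: np.ndarray
    fit_range: tuple[float, float]
    lambda_max: float
    n_pairs: int = 0


def time_normalise(
    axis_signal: np.ndarray,
    events: GaitEvents,
    n_samples_per_stride: int = 100,
) -> np.ndarray:
    """Resample each stride to a fixed number of points.

    Strides are delimited by consecutive stride onsets; each segment is
    linearly interpolated onto ``n_samples_per_stride`` equally spaced phase
    points, so the output length is n_strides * n_samples_per_stride and one
    stride always spans the same number of samples regardless of its
    duration.
    """
    onsets = events.stride_pos
    if len(onsets) < 2:
        raise SignalError("need at least one complete stride to time-normalise")
    out = np.empty((len(onsets) - 1) * n_samples_per_stride)
    for i in range(len(onsets) - 1):
        a, b = float(onsets[i]), float(onsets[i + 1])
        if b - a < 5:
            raise SignalError(f"degenerate stride {i}: only {b - a:.1f} samples")
        # spline over the stride plus margin so the float grid stays interior
        lo = max(0, int(np.floor(a)) - 2)
        hi = min(len(axis_signal) - 1, int(np.ceil(b)) + 2)
        seg = axis_signal[lo : hi + 1]
        spline = CubicSpline(np.arange(lo, hi + 1, dtype=float), seg)
        grid = a + (b - a) * np.arange(n_samples_per_stride) / n_samples_per_stride
        out[i * n_samples_per_stride : (i + 1) * n_samples_per_stride] = spline(grid)
    return out


def average_mutual_information(x: np.ndarray, max_lag: int, bins: int = 64) -> np.ndarray:
    """AMI between x(t) and x(t+lag) for lags 1..max_lag (histogram estimator)."""
    x = np.asarray(x, dtype=float)
    ami = np.empty(max_lag)
    edges = np.histogram_bin_edges(x, bins=bins)
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        h, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        ami[lag - 1] = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return ami


def delay_embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay-coordinate embedding: rows are (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    n = len(x) - (dim - 1) * delay
    if n < 2:
        raise SignalError("series too short for the requested embedding")
    return np.column_stack([x[i * delay : i * delay + n] for i in range(dim)])


def false_nearest_neighbours(
    x: np.ndarray,
    delay: int,
    dim: int,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> float:
    """Fraction of nearest neighbours in dimension ``dim`` that are false.

    A neighbour pair is false when the extra coordinate added by dimension
    dim+1 moves it apart by more than ``rtol`` times its current distance, or
    lands it beyond ``atol`` attractor radii (series SD).
    """
    n_use = len(x) - dim * delay
    if n_use < 50:
        raise SignalError("series too short for FNN analysis")
    emb = delay_embed(x, dim, delay)[:n_use]
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=2)
    d, j = dist[:, 1], idx[:, 1]
    extra = np.abs(x[np.arange(n_use) + dim * delay] - x[j + dim * delay])
    ra = np.std(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, extra / d, np.inf)
    false = (ratio > rtol) | (np.sqrt(d**2 + extra**2) / ra > atol)
    return float(np.mean(false))


def select_embedding(
    series: np.ndarray,
    n_samples_per_stride: int = 100,
    step_period_samples: int | None = None,
    max_dim: int = 10,
    fnn_threshold: float = 0.10,
    max_points: int = 5000,
) -> EmbeddingSpec:
    """Choose delay (first AMI minimum) and dimension (FNN drop below 10 %).

    The delay is the first local minimum of the average mutual information
    (64-bin histogram estimator) within two step periods; when none exists a
    fallback of a quarter step period is used with a warning.  The dimension
    is the smallest d <= max_dim whose false-nearest-neighbour fraction falls
    below ``fnn_threshold``; when none qualifies (e.g. noise-dominated data)
    the fallback is dim = 5.  Long series are subsampled to ``max_points``
    contiguous samples for selection only.
    """
    x = np.asarray(series, dtype=float)
    if len(x) > max_points:
        x = x[:max_points]
    step = step_period_samples or n_samples_per_stride // 2
    tags: list[str] = []

    max_lag = min(2 * step, len(x) // 4)
    ami = average_mutual_information(x, max_lag)
    delay = None
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]:
            delay = i + 1  # ami[0] is lag 1
            break
    if delay is None:
        delay = max(1, step // 4)
        tags.append("ami_fallback")
        warnings.warn("no AMI minimum within 2 step periods; using delay = step/4")
    else:
        tags.append("ami")

    dim = None
    for d in range(2, max_dim + 1):
        if false_nearest_neighbours(x, delay, d) < fnn_threshold:
            dim = d
            break
    if dim is None:
        dim = 5
        tags.append("fnn_fallback")
        warnings.warn("FNN fraction never below threshold up to max_dim; using dim = 5")
    else:
        tags.append("fnn")

    return EmbeddingSpec(
        dim=dim, delay=delay, n_samples_per_stride=n_samples_per_stride, method_tags=tags
    )


def max_lyapunov(
    series: np.ndarray,
    spec: EmbeddingSpec,
    fit_range_strides: tuple[float, float] = (0.0, 0.5),
    horizon_strides: float = 10.0,
    min_pairs: int = 100,
) -> DivergenceCurve:
    """Maximum Lyapunov exponent via nearest-neighbour divergence.

    For every embedded point the nearest neighbour with temporal separation
    greater than one stride (Theiler window) is found; the mean ln distance
    between pairs is tracked over ``horizon_strides`` and the exponent is the
    least-squares slope over ``fit_range_strides``, per stride.  Deterministic
    for a given series (KD-tree neighbour search has no randomness).
    """
    x = np.asarray(series, dtype=float)
    sps = spec.n_samples_per_stride
    emb = delay_embed(x, spec.dim, spec.delay)
    M = len(emb)
    theiler = sps

    k = min(M, 2 * theiler + 2)
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=k)
    rows = np.arange(M)
    valid_mask = np.abs(idx - rows[:, None]) > theiler
    has_nb = valid_mask.any(axis=1)
    first = np.argmax(valid_mask, axis=1)
    nb = idx[rows, first]
    i_idx = rows[has_nb]
    j_idx = nb[has_nb]
    if len(i_idx) < min_pairs:
        raise SignalError(f"only {len(i_idx)} valid neighbour pairs (< {min_pairs})")

    # evaluation offsets: dense through the fit range, coarser out to horizon
    fit_end = int(np.ceil(fit_range_strides[1] * sps))
    coarse = max(1, sps // 10)
    offsets = np.unique(
        np.concatenate(
            [np.arange(0, fit_end + 1), np.arange(0, int(horizon_strides * sps) + 1, coarse)]
        )
    )
    offsets = offsets[offsets < M]

    times = offsets / sps
    mld = np.full(len(offsets), np.nan)
    tiny = np.finfo(float).tiny
    for n, k_off in enumerate(offsets):
        ok = (i_idx + k_off < M) & (j_idx + k_off < M)
        if ok.sum() < min_pairs:
            continue
        d = np.linalg.norm(emb[i_idx[ok] + k_off] - emb[j_idx[ok] + k_off], axis=1)
        mld[n] = float(np.mean(np.log(np.maximum(d, tiny))))

    fit_mask = (
        (times >= fit_range_strides[0]) & (times <= fit_range_strides[1]) & np.isfinite(mld)
    )
    if fit_mask.sum() < 2:
        raise SignalError("divergence curve too short for slope fit")
    slope = float(np.polyfit(times[fit_mask], mld[fit_mask], 1)[0])

    keep = np.isfinite(mld)
    return DivergenceCurve(
        time=times[keep],
        mean_log_divergence=mld[keep],
        fit_range=tuple(fit_range_strides),
        lambda_max=slope,
        n_pairs=int(len(i_idx)),
    )


def stability_per_axis(
    oriented,
    events: GaitEvents,
    spec: EmbeddingSpec | None = None,
    samples_per_stride: int = 100,
    fit_range_strides: tuple[float, float] = (0.0, 0.5),
) -> dict[str, DivergenceCurve]:
    """Per-axis (VT, ML, AP) Lyapunov exponents of the acceleration signal.

    When no :class:`EmbeddingSpec` is given one is selected from the VT
    series and reused for all axes (the three share the gait dynamics'
    time scales).
    """
    step_period = int(round(events.mean_step_s * events.fs))
    out: dict[str, DivergenceCurve] = {}
    series = {
        axis: time_normalise(oriented.acc_axis(axis), events, samples_per_stride)
        for axis in ("VT", "ML", "AP")
    }
    if spec is None:
        spec = select_embedding(
            series["VT"],
            n_samples_per_stride=samples_per_stride,
            step_period_samples=samples_per_stride // 2,
        )
    for axis in ("VT", "ML", "AP"):
        out[axis] = max_lyapunov(series[axis], spec, fit_range_strides=fit_range_strides)
    return out
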