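import warnings

import numpy as np
import pytest

from trunkgait.errors import SignalError
from trunkgait.stability import (
    EmbeddingSpec,
    average_mutual_information,
    delay_embed,
    false_nearest_neighbours,
    max_lyapunov,
    select_embedding,
    time_normalise,
)

from oracles import benettin_lyapunov, histogram_ami, lorenz_series


@pytest.fixture(scope="module")
def lorenz_x():
    return lorenz_series(6000)[:, 0]


def test_time_normalise_fixed_length(default_gait):
    oriented, events, _ = default_gait
    out = time_normalise(oriented.acc_VT, events, 100)
    assert len(out) == 300 * 100


def test_time_normalise_identity_for_constant_period():
    """Resampling a constant-period sine back to its own length is the
    identity up to small interpolation error."""
    from trunkgait.events import GaitEvents

    fs, P = 200.0, 200  # stride period exactly 1 s
    x = np.sin(2 * np.pi * np.arange(8000) / P)
    steps = np.arange(0, 8000, P // 2)
    ev = GaitEvents(step_idx=steps, stride_idx=steps[::2], mean_step_s=0.5,
                    mean_stride_s=1.0, fs=fs)
    out = time_normalise(x, ev, P)
    expected = np.sin(2 * np.pi * np.arange(len(out)) / P)
    assert np.max(np.abs(out - expected)) < 1e-3


def test_ami_minimum_of_sine_near_quarter_period():
    P = 80
    x = np.sin(2 * np.pi * np.arange(8000) / P)
    ami = average_mutual_information(x, 2 * P)
    first = next(
        i + 1 for i in range(1, len(ami) - 1) if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]
    )
    assert abs(first - P / 4) <= 0.2 * (P / 4)
    # the histogram estimator agrees with a direct double-loop computation
    assert ami[9] == pytest.approx(histogram_ami(x, 10), abs=1e-12)


def test_fnn_selects_low_dimension_for_lorenz(lorenz_x):
    spec = select_embedding(lorenz_x, n_samples_per_stride=100, step_period_samples=100)
    assert spec.dim <= 5
    assert "fnn" in spec.method_tags
    # direct FNN check at the selected dimension
    assert false_nearest_neighbours(lorenz_x[:5000], spec.delay, spec.dim) < 0.10


def test_white_noise_triggers_fallback_embedding():
    rng = np.random.default_rng(0)
    wn = rng.standard_normal(5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = select_embedding(wn, n_samples_per_stride=100, step_period_samples=100)
    assert "fnn_fallback" in spec.method_tags
    assert spec.dim == 5


def test_periodic_gait_has_near_zero_lyapunov(perfect_gait):
    oriented, events, _ = perfect_gait
    series = time_normalise(oriented.acc_VT, events, 100)
    spec = EmbeddingSpec(dim=5, delay=25, n_samples_per_stride=100)
    curve = max_lyapunov(series, spec)
    assert curve.lambda_max <= 0.05


def test_lorenz_benchmark_matches_perturbation_oracle(lorenz_x):
    """Divergence-curve estimate vs an independent two-trajectory
    perturbation-growth computation on the same dynamics (per unit time;
    the series is treated as 100 samples per time unit).  The slope is fit
    on the post-transient linear regime of the divergence curve."""
    oracle = benettin_lyapunov()
    assert oracle == pytest.approx(0.906, abs=0.05)  # literature value
    spec = EmbeddingSpec(dim=5, delay=11, n_samples_per_stride=100)
    curve = max_lyapunov(lorenz_x, spec, fit_range_strides=(0.5, 2.0))
    assert curve.lambda_max == pytest.approx(oracle, abs=0.2)


def test_lyapunov_amplitude_invariant(default_gait):
    oriented, events, _ = default_gait
    series = time_normalise(oriented.acc_VT, events, 100)
    spec = EmbeddingSpec(dim=5, delay=25, n_samples_per_stride=100)
    a = max_lyapunov(series, spec).lambda_max
    b = max_lyapunov(series * 123.4, spec).lambda_max
    assert a == pytest.approx(b, abs=1e-6)


def test_lyapunov_deterministic(default_gait):
    oriented, events, _ = default_gait
    series = time_normalise(oriented.acc_ML, events, 100)
    spec = EmbeddingSpec(dim=5, delay=25, n_samples_per_stride=100)
    assert max_lyapunov(series, spec).lambda_max == max_lyapunov(series, spec).lambda_max


def test_default_gait_stability_in_reference_band(default_gait):
    oriented, events, _ = default_gait
    series = time_normalise(oriented.acc_VT, events, 100)
    spec = select_embedding(series, n_samples_per_stride=100, step_period_samples=50)
    lam = max_lyapunov(series, spec).lambda_max
    assert 0.9 <= lam <= 1.6


def test_too_short_series_rejected():
    with pytest.raises(SignalError):
        delay_embed(np.arange(5.0), dim=5, delay=10)
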