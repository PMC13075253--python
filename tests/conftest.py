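import warnings

import numpy as np
import pytest

from trunkgait.events import detect_steps, truncate_strides
from trunkgait.orientation import estimate_tilt, reorient
from trunkgait.synthetic import SignalGenParams, calibrate_default_adult, gen_walk_recording

# embedding-selection fallbacks warn by design on some fixtures
warnings.filterwarnings("ignore", message="no AMI minimum")
warnings.filterwarnings("ignore", message="FNN fraction never")


def oriented_events(params: SignalGenParams, n_strides: int | None = 300):
    """Generate, reorient and (optionally) truncate one recording."""
    rec, truth = gen_walk_recording(params)
    tilt = estimate_tilt(rec)
    oriented = reorient(rec, tilt)
    events = detect_steps(oriented)
    if n_strides is not None:
        events, oriented = truncate_strides(events, oriented, n_strides)
    return oriented, events, truth


@pytest.fixture(scope="session")
def perfect_gait():
    """Noise-free, jitter-free, fully symmetric walking, 300 strides."""
    params = SignalGenParams(
        asym_alpha=1.0,
        stride_time_jitter_sd=0.0,
        noise_sd=0.0,
        gyro_hf_power=0.0,
        duration_s=330.0,
        seed=0,
    )
    return oriented_events(params)


@pytest.fixture(scope="session")
def default_gait():
    """The packaged realistic-adult walking signal, 300 strides."""
    return oriented_events(calibrate_default_adult(seed=1))


@pytest.fixture(scope="session")
def default_cohort():
    from trunkgait.synthetic import gen_cohort

    return gen_cohort(seed=7)
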