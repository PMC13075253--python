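"""Calibration sweep for the packaged 'realistic adult' generator defaults.

Runs the full pipeline over a grid of generator parameters and prints the
per-setting multi-seed means of the twelve outcomes, so the defaults in
``trunkgait.synthetic.calibrate_default_adult`` can be chosen to land inside
the healthy-adult reference bands for symmetry and stability.

Usage:  python scripts/calibrate.py [--seeds N] [--quick]
"""

import argparse
import itertools

import numpy as np
import pandas as pd

from trunkgait.pipeline import PipelineConfig, process_recording
from trunkgait.synthetic import SignalGenParams, gen_walk_recording


def run_setting(asym, jitter, noise, hf, seeds, duration=330.0):
    rows = []
    cfg = PipelineConfig()
    for s in range(seeds):
        params = SignalGenParams(
            asym_alpha=asym,
            stride_time_jitter_sd=jitter,
            noise_sd=noise,
            gyro_hf_power=hf,
            duration_s=duration,
            seed=s,
        )
        rec, _ = gen_walk_recording(params)
        rows.append(process_recording(rec, cfg))
    df = pd.DataFrame(rows)
    cols = [c for c in df.columns if c.endswith(("_VT", "_ML", "_AP"))]
    return df[cols].mean()


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=5)
    ap.add_argument("--quick", action="store_true", help="coarse grid, fewer seeds")
    ap.add_argument("--asym", type=float, nargs="+", default=[0.82, 0.86, 0.90])
    ap.add_argument("--jitter", type=float, nargs="+", default=[0.010, 0.015, 0.020])
    ap.add_argument("--noise", type=float, nargs="+", default=[0.35, 0.45])
    ap.add_argument("--hf", type=float, nargs="+", default=[0.35])
    args = ap.parse_args()
    seeds = 2 if args.quick else args.seeds

    for asym, jit, noi, hf in itertools.product(args.asym, args.jitter, args.noise, args.hf):
        m = run_setting(asym, jit, noi, hf, seeds)
        print(
            f"asym={asym} jitter={jit} noise={noi} hf={hf} | "
            f"stepVT={m['step_symmetry_VT']:.3f} strideVT={m['stride_symmetry_VT']:.3f} "
            f"stepML={m['step_symmetry_ML']:.3f} lamVT={m['stability_VT']:.3f} "
            f"lamML={m['stability_ML']:.3f} lamAP={m['stability_AP']:.3f} "
            f"sparcVT={m['smoothness_VT']:.3f}"
        )


if __name__ == "__main__":
    main()
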