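"""End-to-end orchestration: recording -> gait-quality row, cohort -> tables.

``process_recording`` chains orientation, step detection, truncation to a
fixed stride count, and the three metric families into the twelve-outcome
row.  ``analyze_cohort`` runs the full statistical layer over a cohort
table.  Every output carries the configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trunkgait import stats
from trunkgait.covariates import MUSCLE_GROUPS
from trunkgait.errors import TrunkGaitError
from trunkgait.events import detect_steps, truncate_strides
from trunkgait.orientation import estimate_tilt, reorient
from trunkgait.signal_io import GAIT_QUALITY_COLUMNS, IMURecording, UnitConfig, read_cohort, read_recording
from trunkgait.smoothness import smoothness_per_axis
from trunkgait.stability import stability_per_axis
from trunkgait.symmetry import symmetry_per_axis

logger = logging.getLogger(__name__)

AXES = ("VT", "ML", "AP")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters, hashable for provenance."""

    n_strides: int = 300
    prominence_k: float = 0.3
    f_band: tuple[float, float] = (1.0, 3.0)
    gravity_window_s: float = 30.0
    lowpass_hz: float = 0.1
    window_frac: float = 0.25
    samples_per_stride: int = 100
    fit_range_strides: tuple[float, float] = (0.0, 0.5)
    max_dim: int = 10
    fnn_threshold: float = 0.10
    sparc_fc: float = 10.0
    sparc_amp_threshold: float = 0.05
    sparc_mode: str = "whole"
    alpha: float = 0.05
    bootstrap_B: int = 2000
    seed: int = 0
    strict: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_recording(
    source: str | Path | IMURecording,
    config: PipelineConfig | None = None,
    unit_config: UnitConfig | None = None,
) -> dict:
    """Compute the twelve gait-quality outcomes for one recording.

    Returns a flat dict with subject_id, the outcome columns, QC flags and
    the config hash.  In permissive mode (default) a stage failure yields a
    row of missing outcomes plus an ``error`` entry; strict mode re-raises.
    """
    config = config or PipelineConfig()
    row: dict = {c: np.nan for c in GAIT_QUALITY_COLUMNS}
    row["config_hash"] = config.config_hash
    row["qc_flags"] = ""
    row["error"] = ""
    try:
        rec = source if isinstance(source, IMURecording) else read_recording(source, unit_config)
        row["subject_id"] = rec.subject_id

        tilt = estimate_tilt(rec, window_s=config.gravity_window_s, lowpass_hz=config.lowpass_hz)
        oriented = reorient(rec, tilt)
        events = detect_steps(
            oriented, prominence_k=config.prominence_k, f_band=config.f_band
        )
        events, oriented = truncate_strides(events, oriented, config.n_strides)

        sym = symmetry_per_axis(oriented, events, window_frac=config.window_frac)
        for ax in AXES:
            row[f"step_symmetry_{ax}"] = sym[ax].ad1
            row[f"stride_symmetry_{ax}"] = sym[ax].ad2

        stab = stability_per_axis(
            oriented,
            events,
            samples_per_stride=config.samples_per_stride,
            fit_range_strides=config.fit_range_strides,
        )
        for ax in AXES:
            row[f"stability_{ax}"] = stab[ax].lambda_max

        smo = smoothness_per_axis(
            oriented,
            events,
            fc=config.sparc_fc,
            amp_threshold=config.sparc_amp_threshold,
            mode=config.sparc_mode,
        )
        for ax in AXES:
            row[f"smoothness_{ax}"] = smo[ax].value

        flags = list(events.qc_flags)
        for ax in AXES:
            flags.extend(f"{ax}:{fl}" for fl in sym[ax].flags)
        row["qc_flags"] = ";".join(flags)
    except TrunkGaitError as exc:
        if config.strict:
            raise
        logger.error("processing failed: %s", exc)
        row["error"] = str(exc)
        row.setdefault("subject_id", "")
    return row


def analyze_cohort(
    cohort: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full cohort-level statistical analysis.

    Returns a bundle of tidy DataFrames: ``age_models`` (one row per
    outcome), ``ancova`` (group F/p/omega^2 with bootstrap CI), ``posthoc``
    (only outcomes with a significant group effect), ``delta_r2`` (MET,
    MS_average, MS_diff blocks), and ``muscle_models``; plus the config
    hash.  Missing block columns are skipped with a warning.
    """
    config = config or PipelineConfig()
    df = read_cohort(cohort) if not isinstance(cohort, pd.DataFrame) else cohort
    outcomes = [c for c in GAIT_QUALITY_COLUMNS if c in df.columns and df[c].notna().sum() >= 20]

    age_rows, ancova_rows, posthoc_frames, block_rows, muscle_frames = [], [], [], [], []
    for outcome in outcomes:
        res = stats.fit_age_model(df, outcome, alpha=config.alpha)
        age_rows.append(dataclasses.asdict(res))

        anc = stats.ancova_group(
            df, outcome, bootstrap_B=config.bootstrap_B, seed=config.seed
        )
        d = dataclasses.asdict(anc)
        d.pop("group_means_adj", None)
        ancova_rows.append(d)
        if anc.p_group < config.alpha:
            ph = stats.posthoc_pairwise(df, outcome)
            tab = ph.contrasts.copy()
            tab.insert(0, "outcome", outcome)
            posthoc_frames.append(tab)

        use_quad = res.quad_age is not None
        for block in ("MET", "MS_average", "MS_diff"):
            if block not in df.columns or df[block].notna().sum() == 0:
                logger.warning("block column %s missing; skipped for %s", block, outcome)
                continue
            br = stats.incremental_block(df, outcome, block, alpha=config.alpha, use_quad=use_quad)
            block_rows.append(dataclasses.asdict(br))

        for measure in ("ms_average", "ms_diff"):
            if any(f"{g}_{measure}" in df.columns for g in MUSCLE_GROUPS):
                mt = stats.muscle_specific_models(
                    df, outcome, MUSCLE_GROUPS, measure=measure, alpha=config.alpha, use_quad=use_quad
                )
                mt.insert(0, "outcome", outcome)
                muscle_frames.append(mt)

    return {
        "age_models": pd.DataFrame(age_rows),
        "ancova": pd.DataFrame(ancova_rows),
        "posthoc": pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame(),
        "delta_r2": pd.DataFrame(block_rows),
        "muscle_models": pd.concat(muscle_frames, ignore_index=True) if muscle_frames else pd.DataFrame(),
        "config_hash": config.config_hash,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write an analyze_cohort bundle as CSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": bundle["config_hash"], "tables": []}
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
            manifest["tables"].append(path.name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
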