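"""File formats and the end-to-end feature-extraction pipeline.

Interchange is plain CSV/JSON throughout: landmark tracks and trajectories as
CSV, trial schedules and ground truth as JSON, spectral features as a wide
CSV (``subject_id, trial_id, band_fraction, sum_norm_01.., var_norm_01..``).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .conceft import (
    ConceFTFeatures,
    average_trials,
    band_power_fraction,
    conceft_of_trajectory,
    default_freq_grid,
    extract_features,
    relative_power_spectrum,
)
from .config import PipelineConfig
from .errors import SchemaError
from .synthetic import LANDMARK_COLUMNS, LandmarkTrack
from .trajectory import (
    Mask,
    compute_nic,
    decimate,
    detect_blinks,
    detrend_repeated_median,
    interpolate_blinks,
    lowpass,
    select_trial_segments,
    slice_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "read_schedule_json",
    "write_schedule_json",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "features_frame",
    "preprocess_trajectory",
    "run_pipeline",
]


def read_landmark_csv(path, fps: float | None = None) -> LandmarkTrack:
    """Load a landmark track; schema and time monotonicity are enforced."""
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"landmark CSV is missing columns: {missing}")
    df["detected"] = df["detected"].astype(bool)
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SchemaError("time_s must be strictly increasing")
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 240.0
    return LandmarkTrack(df[LANDMARK_COLUMNS].copy(), float(round(fps, 6)))


def write_landmark_csv(path, track: LandmarkTrack) -> None:
    track.frames.to_csv(path, index=False)


def read_schedule_json(path) -> list[dict]:
    with open(path) as fh:
        sched = json.load(fh)
    for entry in sched:
        for key in ("trial_id", "onset_s", "offset_s"):
            if key not in entry:
                raise SchemaError(f"schedule entry missing {key!r}")
    return sched


def write_schedule_json(path, schedule: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(schedule, fh, indent=1)


def write_trajectory_csv(path, traj) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(traj)),
            "time_s": traj.time_s,
            "nic_x": traj.x,
            "nic_y": traj.y,
            "mask": traj.mask.astype(int),
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path, fps: float | None = None):
    from .trajectory import GazeTrajectory

    df = pd.read_csv(path)
    for col in ("time_s", "nic_x", "nic_y", "mask"):
        if col not in df.columns:
            raise SchemaError(f"trajectory CSV is missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 240.0
    return GazeTrajectory(
        df["nic_x"].to_numpy(float),
        df["nic_y"].to_numpy(float),
        float(round(fps, 6)),
        df["mask"].to_numpy(np.int8),
        t,
    )


def features_frame(rows: list[dict]) -> pd.DataFrame:
    """Wide feature table: one row per (subject, trial) with 28 feature columns."""
    out = []
    for row in rows:
        feats: ConceFTFeatures = row["features"]
        rec = {"subject_id": row["subject_id"], "trial_id": feats.trial_id}
        if "band_fraction" in row:
            rec["band_fraction"] = row["band_fraction"]
        for k in range(14):
            rec[f"sum_norm_{k + 1:02d}"] = feats.sum_norm[k]
        for k in range(14):
            rec[f"var_norm_{k + 1:02d}"] = feats.var_norm[k]
        out.append(rec)
    return pd.DataFrame(out)


def preprocess_trajectory(track: LandmarkTrack, config: PipelineConfig):
    """Landmarks -> clean detrended NIC at the spectral analysis rate."""
    traj = compute_nic(track, eye=config.eye, scale=config.nic_scaling)
    blink_mask, blink_intervals = detect_blinks(
        track, config.ear_threshold, config.blink_pad_frames, eye=config.eye
    )
    logger.info(
        "blink detection: %d intervals, %d frames flagged",
        len(blink_intervals),
        int(blink_mask.sum()),
    )
    traj = interpolate_blinks(traj, blink_mask)
    traj = lowpass(traj, config.lowpass_cutoff_hz, config.lowpass_order)
    factor = max(1, int(round(traj.fps / config.analysis_rate_hz)))
    traj = decimate(traj, factor)
    traj = detrend_repeated_median(traj, config.detrend_window_s)
    return traj, blink_intervals


def run_pipeline(
    track: LandmarkTrack,
    stimulus_schedule: list[dict],
    config: PipelineConfig | None = None,
) -> dict:
    """Full extraction: landmarks -> per-trial 28-feature vectors + averages.

    Returns a dict with per-trial entries (``features``, ``band_fraction``,
    ``relative_power``, ``n_valid_frames``), the averaged ``T1+T2`` features
    when both trials are present, and the frequency grid.
    """
    config = config or PipelineConfig()
    traj, blink_intervals = preprocess_trajectory(track, config)
    grid = default_freq_grid(
        config.freq_grid_lo_hz, config.freq_grid_hi_hz, config.freq_grid_step_hz
    )
    segments = select_trial_segments(traj, stimulus_schedule)
    result: dict = {"trials": {}, "freq_grid": grid, "n_blinks": len(blink_intervals)}
    feats_by_trial: dict[str, ConceFTFeatures] = {}
    for trial_id, rng in segments:
        sub = slice_trajectory(traj, rng)
        tfr = conceft_of_trajectory(
            sub,
            n_windows=config.conceft_n_windows,
            n_projections=config.conceft_n_projections,
            freq_grid=grid,
            seed=config.seed,
            window_s=config.conceft_window_s,
            hop=config.conceft_hop,
            squeeze_threshold=config.squeeze_threshold,
        )
        feats = extract_features(tfr, trial_id=trial_id)
        feats_by_trial[trial_id] = feats
        result["trials"][trial_id] = {
            "features": feats,
            "band_fraction": band_power_fraction(tfr, config.band_lo_hz, config.band_hi_hz),
            "relative_power": relative_power_spectrum(tfr),
            "n_valid_frames": int(tfr.frame_mask.sum()),
        }
        logger.info(
            "trial %s: %d/%d valid TF frames",
            trial_id,
            int(tfr.frame_mask.sum()),
            len(tfr.frame_mask),
        )
    if "T1" in feats_by_trial and "T2" in feats_by_trial:
        result["trials"]["T1+T2"] = {
            "features": average_trials(feats_by_trial["T1"], feats_by_trial["T2"]),
            "band_fraction": float(
                np.mean(
                    [result["trials"][t]["band_fraction"] for t in ("T1", "T2")]
                )
            ),
            "relative_power": (
                result["trials"]["T1"]["relative_power"]
                + result["trials"]["T2"]["relative_power"]
            )
            / 2.0,
            "n_valid_frames": sum(
                result["trials"][t]["n_valid_frames"] for t in ("T1", "T2")
            ),
        }
    return result
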