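"""Reusable study setups: simulated cohorts and planted-signal benchmarks.

These functions define the conditions under which the pipeline is exercised
end-to-end: a saccadic-pursuit cohort versus a smooth-pursuit cohort on the
clinical stimulus (16 deg amplitude, 2.5 s pauses, 2 cycles, 11 deg/s for T1
and 16 deg/s for T2, 240 fps), and feature-space benchmarks for the
classification and severity estimators.
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .config import PipelineConfig
from .groupstats import SubjectRecord
from .io import run_pipeline

__all__ = [
    "t1_stimulus",
    "t2_stimulus",
    "sp_profile",
    "smooth_profile",
    "simulate_subject",
    "simulate_sp_study",
    "gaussian_cohorts",
    "planted_severity_cohort",
]

AMPLITUDE_DEG = 16.0
PAUSE_S = 2.5
N_CYCLES = 2
FPS = 240.0
T1_SPEED_DPS = 11.0
T2_SPEED_DPS = 16.0


def t1_stimulus(fps: float = FPS) -> syn.StimulusTrace:
    return syn.generate_stimulus(AMPLITUDE_DEG, T1_SPEED_DPS, PAUSE_S, N_CYCLES, fps)


def t2_stimulus(fps: float = FPS) -> syn.StimulusTrace:
    return syn.generate_stimulus(AMPLITUDE_DEG, T2_SPEED_DPS, PAUSE_S, N_CYCLES, fps)


def sp_profile(seed: int, **overrides) -> syn.SimProfile:
    """Saccadic-pursuit subject: gain 0.6 with 2 Hz catch-up saccades."""
    kw = dict(
        pursuit_gain=0.6,
        catchup_rate_hz=2.0,
        blink_rate_hz=0.2,
        drift_amp_px=2.0,
        noise_sd_px=0.1,
        gaze_noise_sd_deg=0.05,
        seed=seed,
    )
    kw.update(overrides)
    return syn.SimProfile(**kw)


def smooth_profile(seed: int, **overrides) -> syn.SimProfile:
    """Healthy pursuit: gain 1, no catch-up saccades."""
    kw = dict(
        pursuit_gain=1.0,
        catchup_rate_hz=0.0,
        blink_rate_hz=0.2,
        drift_amp_px=2.0,
        noise_sd_px=0.1,
        gaze_noise_sd_deg=0.05,
        seed=seed,
    )
    kw.update(overrides)
    return syn.SimProfile(**kw)


def simulate_subject(
    profile: syn.SimProfile,
    stimulus: syn.StimulusTrace | None = None,
    config: PipelineConfig | None = None,
    trial_id: str = "T1",
) -> dict:
    """One subject through the whole pipeline on a single trial."""
    stimulus = stimulus if stimulus is not None else t1_stimulus()
    schedule = [{"trial_id": trial_id, "onset_s": 0.0, "offset_s": stimulus.duration_s}]
    track, truth = syn.simulate_trial(stimulus, profile)
    result = run_pipeline(track, schedule, config)
    out = dict(result["trials"][trial_id])
    out["truth"] = truth
    out["freq_grid"] = result["freq_grid"]
    return out


def simulate_sp_study(
    n_per_group: int = 30,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[SubjectRecord]:
    """Paired saccadic vs smooth cohorts on the T1 stimulus.

    Subject k of each cohort shares the per-subject seed ``seed + k`` so the
    two cohorts are seed-paired.  Returns SubjectRecords carrying the 28
    features, the 1.5-2.5 Hz band fraction and the relative-power spectrum.
    """
    stim = t1_stimulus()
    records = []
    for group, make in (("sp", sp_profile), ("smooth", smooth_profile)):
        for k in range(n_per_group):
            res = simulate_subject(make(seed + k), stim, config)
            records.append(
                SubjectRecord(
                    subject_id=f"{group}{k:03d}",
                    diagnosis="ataxia" if group == "sp" else "control",
                    signs={"saccadic_pursuit": group == "sp"},
                    bars_oculomotor=0.5 if group == "sp" else 0.0,
                    features={"T1": res["features"]},
                    band_fraction=res["band_fraction"],
                    relative_power=res["relative_power"],
                    freq_grid=res["freq_grid"],
                )
            )
    return records


def gaussian_cohorts(
    n_per_group: int = 40,
    n_features: int = 28,
    separation: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian clouds with centers ``separation`` apart
    along the first feature; labels 1 for the shifted cloud."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_group, n_features))
    y = np.repeat([0, 1], n_per_group)
    X[y == 1, 0] += separation
    return X, y


def planted_severity_cohort(
    n_subjects: int = 40,
    noise_frac: float = 0.25,
    seed: int = 0,
    n_features: int = 28,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix with a monotone severity signal planted in the
    1.5-2.5 Hz band columns.

    Scores cycle over {0, 0.5, 1, 1.5, 2}; the four band columns (Sum and
    Var features of the 1.5-2 and 2-2.5 Hz bands) increase linearly with the
    score, contaminated by Gaussian noise of SD ``noise_frac`` times the
    effect range; all other columns are pure noise.
    """
    rng = np.random.default_rng(seed)
    scores = np.tile([0.0, 0.5, 1.0, 1.5, 2.0], n_subjects // 5 + 1)[:n_subjects]
    rng.shuffle(scores)
    X = rng.normal(size=(n_subjects, n_features))
    planted = [1, 2, 15, 16]  # sum/var columns of the 1.5-2 and 2-2.5 Hz bands
    effect_range = 2.0  # score span 0..2 at unit slope
    for col in planted:
        X[:, col] = scores + rng.normal(0.0, noise_frac * effect_range, n_subjects)
    return X, scores
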