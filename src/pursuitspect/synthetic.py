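"""Synthetic smooth-pursuit stimulus, gaze, and facial-landmark simulator.

The clinical task shows a dot that sweeps horizontally across a screen at
constant speed, dwelling at the extremities, while a high-frame-rate camera
records the face.  This module generates (a) the piecewise-linear stimulus
trace, (b) a gaze-angle trace that follows the stimulus with a configurable
pursuit gain, catch-up saccades, optional nystagmus and noise, and (c) a
per-frame facial-landmark track (two eye corners, four eyelid points and an
iris center per eye) with common-mode drift, landmark jitter and blinks —
i.e. everything the downstream trajectory/spectral pipeline consumes, with
ground truth attached.

Saccadic (broken) pursuit is emulated by lowering ``pursuit_gain`` below 1 and
generating catch-up saccades as a Poisson process during dot motion; each
saccade is a short linear ramp that cancels the accumulated position error,
producing the characteristic stair-step trajectory of cerebellar patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "StimulusTrace",
    "SimProfile",
    "EyeGeometry",
    "LandmarkTrack",
    "GazeSimulation",
    "LANDMARK_COLUMNS",
    "generate_stimulus",
    "concatenate_stimuli",
    "simulate_gaze",
    "render_landmarks",
    "inject_blinks",
    "simulate_trial",
]

# Eye landmark naming (per eye): corner_l (p1), lid_up1 (p2), lid_up2 (p3),
# corner_r (p4), lid_lo2 (p5), lid_lo1 (p6).  p2/p6 share an x offset left of
# the eye center, p3/p5 right of it, so the eye-aspect-ratio pairs are
# (p2, p6) and (p3, p5).
_EYE_POINTS = ["corner_l", "corner_r", "lid_up1", "lid_up2", "lid_lo1", "lid_lo2"]

LANDMARK_COLUMNS = (
    ["frame_index", "time_s", "detected"]
    + [f"{eye}_{pt}_{ax}" for eye in ("left", "right") for pt in _EYE_POINTS for ax in ("x", "y")]
    + ["iris_left_x", "iris_left_y", "iris_right_x", "iris_right_y"]
)


@dataclass
class StimulusTrace:
    """Horizontal dot trajectory in degrees, sampled at ``fps``."""

    positions: np.ndarray
    timestamps: np.ndarray
    fps: float
    amplitude_deg: float
    speed_dps: float
    pause_s: float
    n_cycles: int
    #: per-sample True while the dot is moving (slope != 0)
    moving: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def duration_s(self) -> float:
        return 0.0 if len(self) == 0 else float(self.timestamps[-1])


@dataclass
class SimProfile:
    """Behavioral and measurement parameters of one simulated recording.

    ``pursuit_gain`` is the ratio of eye velocity to dot velocity during
    tracking; healthy pursuit is near 1, cerebellar saccadic pursuit is
    emulated with gain ~0.5-0.7 plus catch-up saccades at ``catchup_rate_hz``.
    """

    pursuit_gain: float = 1.0
    catchup_rate_hz: float = 0.0
    #: gamma shape of inter-saccade intervals; 1 = Poisson, larger = more
    #: rhythmic (real catch-up saccades have a refractory period and cluster
    #: around a preferred tempo, which is what puts their power near the rate)
    catchup_regularity: float = 4.0
    saccade_duration_s: float = 0.05
    blink_rate_hz: float = 0.0
    blink_duration_s: float = 0.3
    blink_iris_shift_px: float = 6.0
    drift_amp_px: float = 0.0
    noise_sd_px: float = 0.0
    gaze_noise_sd_deg: float = 0.0
    nystagmus_hz: float = 0.0
    nystagmus_amp_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pursuit_gain <= 1.0:
            raise InvalidParameterError(f"pursuit_gain must be in [0, 1], got {self.pursuit_gain}")
        if self.catchup_regularity <= 0:
            raise InvalidParameterError("catchup_regularity must be > 0")
        for name in (
            "catchup_rate_hz",
            "saccade_duration_s",
            "blink_rate_hz",
            "blink_duration_s",
            "drift_amp_px",
            "noise_sd_px",
            "gaze_noise_sd_deg",
            "nystagmus_hz",
            "nystagmus_amp_deg",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EyeGeometry:
    """Pixel geometry of the simulated eyes on the camera sensor."""

    corner_left_px: tuple[float, float] = (100.0, 100.0)
    corner_right_px: tuple[float, float] = (140.0, 100.0)
    px_per_degree: float = 2.0
    open_ear: float = 0.3
    #: horizontal offset of the right eye relative to the left
    interocular_px: float = 60.0

    def __post_init__(self) -> None:
        width = np.hypot(
            self.corner_right_px[0] - self.corner_left_px[0],
            self.corner_right_px[1] - self.corner_left_px[1],
        )
        if width <= 0:
            raise InvalidParameterError("eye corner distance must be > 0")
        if self.px_per_degree <= 0:
            raise InvalidParameterError("px_per_degree must be > 0")

    @property
    def eye_width_px(self) -> float:
        return float(
            np.hypot(
                self.corner_right_px[0] - self.corner_left_px[0],
                self.corner_right_px[1] - self.corner_left_px[1],
            )
        )


@dataclass
class LandmarkTrack:
    """Per-frame eye and iris landmarks, the raw input of the pipeline.

    ``frames`` follows the landmark CSV schema (:data:`LANDMARK_COLUMNS`):
    frame_index, time_s, detected, then x/y pairs for each eye's six landmarks
    and the two iris centers.  Undetected frames keep NaN coordinates.
    """

    frames: pd.DataFrame
    fps: float

    def __post_init__(self) -> None:
        missing = [c for c in LANDMARK_COLUMNS if c not in self.frames.columns]
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"landmark frame is missing columns: {missing}")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be > 0")
        t = self.frames["time_s"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            from .errors import SchemaError

            raise SchemaError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def detected(self) -> np.ndarray:
        return self.frames["detected"].to_numpy(bool)

    @property
    def time_s(self) -> np.ndarray:
        return self.frames["time_s"].to_numpy(float)

    def eye_landmarks(self, eye: str = "left") -> np.ndarray:
        """Return (n, 6, 2) array ordered p1..p6 for the EAR convention.

        p1/p4 are the corners, p2/p3 the upper lid, p6/p5 the lower lid,
        with (p2, p6) and (p3, p5) the two vertical pairs.
        """
        order = ["corner_l", "lid_up1", "lid_up2", "corner_r", "lid_lo2", "lid_lo1"]
        cols = [f"{eye}_{pt}_{ax}" for pt in order for ax in ("x", "y")]
        arr = self.frames[cols].to_numpy(float)
        return arr.reshape(len(self.frames), 6, 2)

    def iris(self, eye: str = "left") -> np.ndarray:
        cols = [f"iris_{eye}_x", f"iris_{eye}_y"]
        return self.frames[cols].to_numpy(float)

    def copy(self) -> "LandmarkTrack":
        return LandmarkTrack(self.frames.copy(), self.fps)


@dataclass
class GazeSimulation:
    """Gaze-angle trace plus the ground truth used to score detectors."""

    angles: np.ndarray
    saccade_times_s: list[float]

    def __len__(self) -> int:
        return len(self.angles)


def generate_stimulus(
    amplitude_deg: float,
    speed_dps: float,
    pause_s: float,
    n_cycles: int,
    fps: float,
) -> StimulusTrace:
    """Piecewise-linear horizontal dot trajectory.

    Each cycle runs center -> +A/2 -> (pause) -> -A/2 -> (pause) -> center at
    constant speed, so one cycle lasts ``2*A/speed + 2*pause`` seconds and a
    trial covers ``n_cycles`` of them.
    """
    if fps <= 0 or speed_dps <= 0:
        raise InvalidParameterError("fps and speed_dps must be positive")
    if amplitude_deg <= 0 or pause_s < 0 or n_cycles < 0:
        raise InvalidParameterError("amplitude must be positive, pause and cycles nonnegative")

    half = amplitude_deg / 2.0
    if n_cycles == 0:
        empty = np.empty(0)
        return StimulusTrace(empty, empty.copy(), fps, amplitude_deg, speed_dps, pause_s, 0, empty.astype(bool))

    # breakpoints of one cycle: times (s) and positions (deg)
    t_half = half / speed_dps
    t_full = amplitude_deg / speed_dps
    cyc_t = np.array([0.0, t_half, t_half + pause_s, t_half + pause_s + t_full,
                      t_half + 2 * pause_s + t_full, 2 * t_half + 2 * pause_s + t_full])
    cyc_p = np.array([0.0, half, half, -half, -half, 0.0])
    cycle_len = cyc_t[-1]

    bp_t = [0.0]
    bp_p = [0.0]
    for c in range(n_cycles):
        bp_t.extend(cyc_t[1:] + c * cycle_len)
        bp_p.extend(cyc_p[1:])
    bp_t = np.asarray(bp_t)
    bp_p = np.asarray(bp_p)

    total = n_cycles * cycle_len
    n = int(np.floor(total * fps)) + 1
    t = np.arange(n) / fps
    pos = np.interp(t, bp_t, bp_p)

    # a sample is "moving" when it falls inside a nonzero-slope segment
    seg = np.clip(np.searchsorted(bp_t, t, side="right") - 1, 0, len(bp_t) - 2)
    seg_slope = np.diff(bp_p) / np.diff(bp_t)
    moving = np.abs(seg_slope[seg]) > 1e-12

    return StimulusTrace(pos, t, fps, amplitude_deg, speed_dps, pause_s, n_cycles, moving)


def concatenate_stimuli(traces: list[StimulusTrace], gap_s: float = 1.0) -> tuple[StimulusTrace, list[dict]]:
    """Join trial stimuli into one recording with stationary gaps.

    Returns the combined trace plus a schedule ``[{trial_id, onset_s,
    offset_s}, ...]`` suitable for trial segmentation downstream.
    """
    if not traces:
        raise InvalidParameterError("need at least one trace")
    fps = traces[0].fps
    gap_n = int(round(gap_s * fps))
    pos_parts: list[np.ndarray] = []
    mov_parts: list[np.ndarray] = []
    schedule = []
    offset = 0
    for k, tr in enumerate(traces):
        if tr.fps != fps:
            raise InvalidParameterError("all traces must share fps")
        schedule.append(
            {
                "trial_id": f"T{k + 1}",
                "onset_s": offset / fps,
                "offset_s": (offset + len(tr) - 1) / fps,
            }
        )
        pos_parts.append(tr.positions)
        mov_parts.append(tr.moving)
        offset += len(tr)
        if k < len(traces) - 1 and gap_n:
            pos_parts.append(np.zeros(gap_n))
            mov_parts.append(np.zeros(gap_n, bool))
            offset += gap_n
    pos = np.concatenate(pos_parts)
    moving = np.concatenate(mov_parts)
    t = np.arange(len(pos)) / fps
    first = traces[0]
    return (
        StimulusTrace(pos, t, fps, first.amplitude_deg, first.speed_dps, first.pause_s,
                      sum(tr.n_cycles for tr in traces), moving),
        schedule,
    )


def simulate_gaze(stimulus: StimulusTrace, profile: SimProfile) -> GazeSimulation:
    """Eye gaze angle following the stimulus under the given pursuit profile.

    The eye moves at ``pursuit_gain`` times the dot velocity; position error
    accumulates and is cancelled by catch-up saccades (linear ramps of
    ``saccade_duration_s``) triggered by a renewal process at mean rate
    ``catchup_rate_hz`` while the dot moves.  Inter-saccade intervals are
    gamma-distributed with shape ``catchup_regularity`` (1 recovers a Poisson
    process); the clock advances only during motion epochs.  Optional
    nystagmus sinusoid and Gaussian gaze noise are added last.  Deterministic
    given ``profile.seed``.
    """
    if len(stimulus) == 0:
        raise InvalidParameterError("stimulus must be non-empty")
    rng = np.random.default_rng([int(profile.seed), 0])
    n = len(stimulus)
    dt = 1.0 / stimulus.fps
    stim = stimulus.positions
    # per-frame stimulus displacement; integrating it at gain 1 reproduces
    # the stimulus exactly (no quadrature error at the slope breakpoints)
    dstim = np.diff(stim, prepend=stim[0])

    sacc_frames = max(1, int(round(profile.saccade_duration_s * stimulus.fps)))
    rate = profile.catchup_rate_hz
    shape = profile.catchup_regularity

    def _next_gap() -> float:
        return float(rng.gamma(shape, 1.0 / (rate * shape)))

    # frames at which a fixation-acquisition saccade is due: when the dot
    # stops, the eye foveates the stationary target after a short latency
    # (otherwise a low-gain eye would sit parked off-target for the whole
    # pause, which real patients do not do)
    fixation_latency = max(1, int(round(0.2 * stimulus.fps)))
    stops = np.flatnonzero(~stimulus.moving[1:] & stimulus.moving[:-1]) + 1
    fixation_due = set((stops + fixation_latency).tolist())

    gaze = np.empty(n)
    pos = stim[0]
    remaining = 0
    step = 0.0
    motion_clock = 0.0
    next_event = _next_gap() if rate > 0 else np.inf
    sacc_times: list[float] = []
    for i in range(n):
        pos += profile.pursuit_gain * dstim[i]
        if stimulus.moving[i]:
            motion_clock += dt
        trigger = False
        if remaining > 0:
            pos += step
            remaining -= 1
        elif stimulus.moving[i] and motion_clock >= next_event:
            trigger = True
            next_event = motion_clock + _next_gap()
        elif i in fixation_due and abs(stim[i] - pos) > 0.1:
            trigger = True
        if trigger:
            err = stim[i] - pos
            step = err / sacc_frames
            remaining = sacc_frames
            sacc_times.append(float(stimulus.timestamps[i]))
        gaze[i] = pos

    if profile.nystagmus_hz > 0 and profile.nystagmus_amp_deg > 0:
        gaze = gaze + profile.nystagmus_amp_deg * np.sin(
            2 * np.pi * profile.nystagmus_hz * stimulus.timestamps
        )
    if profile.gaze_noise_sd_deg > 0:
        gaze = gaze + rng.normal(0.0, profile.gaze_noise_sd_deg, n)
    return GazeSimulation(gaze, sacc_times)


def _eye_frame_columns(eye: str) -> list[str]:
    return [f"{eye}_{pt}_{ax}" for pt in _EYE_POINTS for ax in ("x", "y")]


def render_landmarks(
    gaze_deg: np.ndarray,
    geometry: EyeGeometry,
    profile: SimProfile,
    fps: float = 240.0,
) -> LandmarkTrack:
    """Project a gaze-angle trace onto pixel-space facial landmarks.

    The iris sits at the corner midpoint plus ``gaze * px_per_degree`` on x;
    eyelid landmarks are placed to yield an eye aspect ratio of ``open_ear``.
    Slow head-motion drift is applied to *all* landmarks (common mode, so the
    normalized iris center cancels it); landmark jitter is independent per
    landmark and frame.
    """
    gaze_deg = np.asarray(gaze_deg, float)
    if not np.all(np.isfinite(gaze_deg)):
        raise InvalidParameterError("gaze must be finite")
    rng = np.random.default_rng([int(profile.seed), 2])
    n = len(gaze_deg)
    t = np.arange(n) / fps

    if profile.drift_amp_px > 0:
        fx, fy = rng.uniform(0.05, 0.2, 2)
        phx, phy = rng.uniform(0, 2 * np.pi, 2)
        drift_x = profile.drift_amp_px * np.sin(2 * np.pi * fx * t + phx)
        drift_y = profile.drift_amp_px * np.sin(2 * np.pi * fy * t + phy)
    else:
        drift_x = np.zeros(n)
        drift_y = np.zeros(n)

    cl = np.asarray(geometry.corner_left_px, float)
    cr = np.asarray(geometry.corner_right_px, float)
    w = geometry.eye_width_px
    h = geometry.open_ear * w  # eyelid vertical extent giving EAR = open_ear
    mid = (cl + cr) / 2.0

    data: dict[str, np.ndarray] = {
        "frame_index": np.arange(n),
        "time_s": t,
        "detected": np.ones(n, bool),
    }
    for eye, x_off in (("left", 0.0), ("right", geometry.interocular_px)):
        base = {
            "corner_l": cl + [x_off, 0.0],
            "corner_r": cr + [x_off, 0.0],
            "lid_up1": mid + [x_off - w / 4, h / 2],
            "lid_up2": mid + [x_off + w / 4, h / 2],
            "lid_lo1": mid + [x_off - w / 4, -h / 2],
            "lid_lo2": mid + [x_off + w / 4, -h / 2],
        }
        for pt, xy in base.items():
            noise = (
                rng.normal(0.0, profile.noise_sd_px, (n, 2))
                if profile.noise_sd_px > 0
                else np.zeros((n, 2))
            )
            data[f"{eye}_{pt}_x"] = xy[0] + drift_x + noise[:, 0]
            data[f"{eye}_{pt}_y"] = xy[1] + drift_y + noise[:, 1]
        iris_x = mid[0] + x_off + gaze_deg * geometry.px_per_degree
        noise = (
            rng.normal(0.0, profile.noise_sd_px, (n, 2))
            if profile.noise_sd_px > 0
            else np.zeros((n, 2))
        )
        data[f"iris_{eye}_x"] = iris_x + drift_x + noise[:, 0]
        data[f"iris_{eye}_y"] = mid[1] + drift_y + noise[:, 1]

    frames = pd.DataFrame(data)[LANDMARK_COLUMNS]
    return LandmarkTrack(frames, fps)


def inject_blinks(
    track: LandmarkTrack,
    profile: SimProfile,
    geometry: EyeGeometry | None = None,
) -> tuple[LandmarkTrack, list[tuple[int, int]]]:
    """Overlay Poisson-process blinks; returns the track and truth intervals.

    During each blink the eyelid landmarks of both eyes collapse (EAR drops
    to a tenth of the open value) and the iris centers spike upward and
    sideways by ``blink_iris_shift_px``, mimicking the landmark-detector
    failure mode that contaminates real recordings.  Intervals are half-open
    ``(start_frame, stop_frame)``.
    """
    if len(track) == 0:
        raise InvalidParameterError("track must be non-empty")
    geometry = geometry or EyeGeometry()
    duration = len(track) / track.fps
    if profile.blink_duration_s >= duration:
        raise InvalidParameterError("blink_duration_s must be shorter than the trial")
    if profile.blink_rate_hz == 0:
        return track, []

    rng = np.random.default_rng([int(profile.seed), 1])
    onsets: list[float] = []
    t = float(rng.exponential(1.0 / profile.blink_rate_hz))
    while t < duration - profile.blink_duration_s:
        onsets.append(t)
        t += profile.blink_duration_s + float(rng.exponential(1.0 / profile.blink_rate_hz))

    out = track.copy()
    frames = out.frames
    n = len(frames)
    w = geometry.eye_width_px
    closed_half = 0.1 * geometry.open_ear * w / 2.0  # EAR = open_ear/10 < open_ear/3
    intervals: list[tuple[int, int]] = []
    for onset in onsets:
        a = int(round(onset * track.fps))
        b = min(n, a + max(1, int(round(profile.blink_duration_s * track.fps))))
        intervals.append((a, b))
        sl = slice(a, b)
        for eye in ("left", "right"):
            for up, lo in (("lid_up1", "lid_lo1"), ("lid_up2", "lid_lo2")):
                uy = frames[f"{eye}_{up}_y"].to_numpy(float)
                ly = frames[f"{eye}_{lo}_y"].to_numpy(float)
                mid_y = (uy[sl] + ly[sl]) / 2.0
                # shrink vertical extent around the lid midline
                frames.loc[frames.index[sl], f"{eye}_{up}_y"] = mid_y + closed_half
                frames.loc[frames.index[sl], f"{eye}_{lo}_y"] = mid_y - closed_half
            shift = profile.blink_iris_shift_px
            frames.loc[frames.index[sl], f"iris_{eye}_y"] = (
                frames.loc[frames.index[sl], f"iris_{eye}_y"] + shift
            )
            frames.loc[frames.index[sl], f"iris_{eye}_x"] = (
                frames.loc[frames.index[sl], f"iris_{eye}_x"] + shift
            )
    return out, intervals


def simulate_trial(
    stimulus: StimulusTrace,
    profile: SimProfile,
    geometry: EyeGeometry | None = None,
) -> tuple[LandmarkTrack, dict]:
    """Full simulator path: gaze -> landmarks -> blinks, with ground truth."""
    geometry = geometry or EyeGeometry()
    sim = simulate_gaze(stimulus, profile)
    track = render_landmarks(sim.angles, geometry, profile, fps=stimulus.fps)
    track, blink_intervals = inject_blinks(track, profile, geometry)
    truth = {
        "profile": profile.to_dict(),
        "saccade_times_s": sim.saccade_times_s,
        "blink_intervals": [list(iv) for iv in blink_intervals],
    }
    return track, truth


def write_truth_json(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
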