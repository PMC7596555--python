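"""Normalized-iris-center trajectories: blink handling, filtering, detrending.

The eye position signal is the normalized iris center (NIC): the iris-center
landmark expressed relative to the midpoint of the two eye-corner landmarks,
which cancels common head translation.  By default the offset is additionally
divided by the inter-corner distance of the frame, making the signal
dimensionless and robust to changes in camera distance; pass ``scale=False``
for raw pixels.

Blinks are detected with the eye aspect ratio (EAR), the ratio of the two
eyelid vertical distances to twice the eye width; it collapses when the eye
closes.  Blink frames (and frames where the landmark detector failed) are
bridged by cubic interpolation so the spectral transform sees a gapless
series, but they stay flagged in the mask so their spectral power can be
excluded from feature computation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation

from .errors import (
    DegenerateGeometryError,
    EmptySignalError,
    InvalidParameterError,
)
from .synthetic import LandmarkTrack

logger = logging.getLogger(__name__)

__all__ = [
    "Mask",
    "GazeTrajectory",
    "compute_nic",
    "eye_aspect_ratio",
    "detect_blinks",
    "interpolate_blinks",
    "lowpass",
    "decimate",
    "detrend_repeated_median",
    "select_trial_segments",
]


class Mask(enum.IntEnum):
    """Per-frame status of a gaze sample."""

    VALID = 0
    MISSING = 1
    BLINK_INTERPOLATED = 2


@dataclass
class GazeTrajectory:
    """NIC time series with a per-frame validity mask."""

    x: np.ndarray
    y: np.ndarray
    fps: float
    mask: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.mask) == len(self.time_s) == n):
            raise InvalidParameterError("x, y, mask and time_s must share length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def valid(self) -> np.ndarray:
        return self.mask == Mask.VALID


def compute_nic(track: LandmarkTrack, eye: str = "left", scale: bool = True) -> GazeTrajectory:
    """Normalized iris center relative to the eye-corner midpoint.

    Undetected frames get NaN coordinates and a ``MISSING`` mask.  With
    ``scale=True`` the offset is divided by the per-frame inter-corner
    distance.
    """
    if len(track) == 0:
        raise EmptySignalError("empty landmark track")
    detected = track.detected
    if not detected.any():
        raise EmptySignalError("all frames undetected")

    lms = track.eye_landmarks(eye)
    iris = track.iris(eye)
    p1, p4 = lms[:, 0], lms[:, 3]
    mid = (p1 + p4) / 2.0
    nic = iris - mid
    if scale:
        width = np.linalg.norm(p4 - p1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nic = nic / width[:, None]
    mask = np.where(detected, Mask.VALID, Mask.MISSING).astype(np.int8)
    nic[~detected] = np.nan
    return GazeTrajectory(nic[:, 0].copy(), nic[:, 1].copy(), track.fps, mask, track.time_s.copy())


def eye_aspect_ratio(landmarks: np.ndarray) -> np.ndarray | float:
    """EAR = (||p2-p6|| + ||p3-p5||) / (2 ||p1-p4||) for (..., 6, 2) landmarks."""
    lm = np.asarray(landmarks, float)
    if lm.shape[-2:] != (6, 2):
        raise InvalidParameterError("expected landmarks of shape (..., 6, 2)")
    width = np.linalg.norm(lm[..., 3, :] - lm[..., 0, :], axis=-1)
    if np.any(width[np.isfinite(width)] == 0):
        raise DegenerateGeometryError("coincident eye corners (zero width)")
    v1 = np.linalg.norm(lm[..., 1, :] - lm[..., 5, :], axis=-1)
    v2 = np.linalg.norm(lm[..., 2, :] - lm[..., 4, :], axis=-1)
    ear = (v1 + v2) / (2.0 * width)
    return float(ear) if ear.ndim == 0 else ear


def detect_blinks(
    track: LandmarkTrack,
    ear_threshold: float = 0.2,
    pad_frames: int = 3,
    eye: str = "left",
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flag frames with EAR below threshold, dilated by ``pad_frames``.

    Returns a boolean per-frame blink mask and the list of contiguous blink
    intervals as half-open ``(start, stop)`` frame ranges.  Undetected frames
    are never flagged (they are already unusable and handled as missing).
    """
    if len(track) == 0:
        raise EmptySignalError("empty landmark track")
    ear = eye_aspect_ratio(track.eye_landmarks(eye))
    with np.errstate(invalid="ignore"):
        blink = np.asarray(ear < ear_threshold) & track.detected
    if pad_frames > 0 and blink.any():
        blink = binary_dilation(blink, iterations=pad_frames)
    intervals = _runs(blink)
    return blink, intervals


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def interpolate_blinks(traj: GazeTrajectory, blink_mask: np.ndarray) -> GazeTrajectory:
    """Bridge blink and missing frames with cubic interpolation.

    Interpolated frames are flagged ``BLINK_INTERPOLATED`` — never restored to
    valid — so spectral power can be ignored there later.  Gaps touching the
    sequence boundary are filled by holding the nearest valid value (cubic
    extrapolation would be wild) and logged.
    """
    blink_mask = np.asarray(blink_mask, bool)
    fill = blink_mask | (traj.mask != Mask.VALID)
    if not fill.any():
        return traj
    good = ~fill
    if good.sum() < 4:
        raise EmptySignalError("fewer than 4 valid frames to interpolate from")

    t = traj.time_s
    new_mask = np.where(fill, np.int8(Mask.BLINK_INTERPOLATED), traj.mask).astype(np.int8)
    out = {}
    for name in ("x", "y"):
        v = getattr(traj, name).copy()
        cs = CubicSpline(t[good], v[good])
        idx = np.flatnonzero(fill)
        v[idx] = cs(t[idx])
        first, last = np.flatnonzero(good)[[0, -1]]
        if fill[:first].any() or fill[last + 1 :].any():
            logger.warning("gap touches sequence boundary; holding nearest value")
            v[:first] = v[first]
            v[last + 1 :] = v[last]
        out[name] = v
    return GazeTrajectory(out["x"], out["y"], traj.fps, new_mask, t.copy())


def lowpass(traj: GazeTrajectory, cutoff_hz: float = 8.0, order: int = 4) -> GazeTrajectory:
    """Zero-phase Butterworth low-pass on x and y; masks preserved."""
    if traj.fps <= 2 * cutoff_hz:
        raise InvalidParameterError(
            f"sampling rate {traj.fps} too low for a {cutoff_hz} Hz cutoff"
        )
    sos = sps.butter(order, cutoff_hz, fs=traj.fps, output="sos")

    def _filt(v: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(v)):
            # filter only over the finite span; NaN frames stay NaN
            vv = v.copy()
            fin = np.isfinite(v)
            if fin.sum() >= 15:
                filled = np.interp(np.arange(len(v)), np.flatnonzero(fin), v[fin])
                sm = sps.sosfiltfilt(sos, filled)
                vv[fin] = sm[fin]
            return vv
        return sps.sosfiltfilt(sos, v)

    return replace(traj, x=_filt(traj.x), y=_filt(traj.y))


def decimate(traj: GazeTrajectory, factor: int) -> GazeTrajectory:
    """Keep every ``factor``-th frame (the signal must already be band-limited).

    A frame of the decimated series is valid only if the frame it keeps was
    valid; applied after the anti-aliasing low-pass.
    """
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    if factor == 1:
        return traj
    sl = slice(None, None, factor)
    return GazeTrajectory(
        traj.x[sl].copy(), traj.y[sl].copy(), traj.fps / factor, traj.mask[sl].copy(), traj.time_s[sl].copy()
    )


def _repeated_median_trend(x: np.ndarray, fps: float, window: int) -> np.ndarray:
    """Repeated-median regression trend evaluated at every sample.

    For each sample the window is centered on it (shifted at the edges so a
    full window is always used); slope = median over i of the median over
    j != i of pairwise slopes, intercept = median of x_j - slope * t_j.
    """
    n = len(x)
    w = min(window, n)
    half = (w - 1) // 2
    dt = 1.0 / fps
    t_rel = (np.arange(w) - half) * dt  # times relative to window center
    dT = t_rel[None, :] - t_rel[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_dT = 1.0 / dT
    np.fill_diagonal(inv_dT, np.nan)

    centers = np.clip(np.arange(n), half, n - 1 - (w - 1 - half))
    starts = centers - half
    windows = np.lib.stride_tricks.sliding_window_view(x, w)  # (n-w+1, w)

    trend = np.empty(n)
    # chunk to bound the (chunk, w, w) slope tensor's memory
    chunk = max(1, int(4_000_000 / (w * w)))
    uniq_starts, inverse = np.unique(starts, return_inverse=True)
    slope_u = np.empty(len(uniq_starts))
    icept_u = np.empty(len(uniq_starts))
    for a in range(0, len(uniq_starts), chunk):
        b = min(a + chunk, len(uniq_starts))
        X = windows[uniq_starts[a:b]]  # (c, w)
        S = (X[:, None, :] - X[:, :, None]) * inv_dT  # (c, w, w), NaN diag
        inner = np.nanmedian(S, axis=2)
        slope = np.median(inner, axis=1)
        icept = np.median(X - slope[:, None] * t_rel[None, :], axis=1)
        slope_u[a:b] = slope
        icept_u[a:b] = icept
    # evaluate each sample's trend at its offset from its window center
    off = (np.arange(n) - centers) * dt
    trend = icept_u[inverse] + slope_u[inverse] * off
    return trend


def detrend_repeated_median(traj: GazeTrajectory, window_s: float = 1.0) -> GazeTrajectory:
    """Subtract a robust local linear trend estimated by repeated-median regression.

    Removes slow head drift and the stimulus-following component while being
    insensitive to outliers (breakdown point 50%), leaving the oscillatory
    content for the spectral stage.  The window is truncated (with a warning)
    if it exceeds the signal.
    """
    n = len(traj)
    w = int(round(window_s * traj.fps))
    if w < 5:
        raise InvalidParameterError("window must span at least 5 samples")
    if w > n:
        logger.warning("detrend window longer than signal; truncating to %d samples", n)
        w = n
    if w % 2 == 0:
        w += 1
        w = min(w, n if n % 2 == 1 else n - 1)
    x = np.nan_to_num(traj.x, nan=0.0)
    y = np.nan_to_num(traj.y, nan=0.0)
    tx = _repeated_median_trend(x, traj.fps, w)
    ty = _repeated_median_trend(y, traj.fps, w)
    out_x = traj.x - tx
    out_y = traj.y - ty
    return replace(traj, x=out_x, y=out_y)


def select_trial_segments(
    traj: GazeTrajectory, stimulus_schedule: list[dict]
) -> list[tuple[str, tuple[int, int]]]:
    """Frame ranges (half-open) covering each scheduled trial.

    The schedule lists ``{"trial_id", "onset_s", "offset_s"}`` entries; ranges
    outside the recording are clipped with a warning.
    """
    n = len(traj)
    out = []
    for entry in stimulus_schedule:
        a = int(round(entry["onset_s"] * traj.fps))
        b = int(round(entry["offset_s"] * traj.fps)) + 1
        if a < 0 or b > n:
            logger.warning("trial %s schedule clipped to recording", entry["trial_id"])
        a, b = max(0, a), min(n, b)
        if b > a:
            out.append((str(entry["trial_id"]), (a, b)))
    return out


def slice_trajectory(traj: GazeTrajectory, frame_range: tuple[int, int]) -> GazeTrajectory:
    a, b = frame_range
    return GazeTrajectory(
        traj.x[a:b].copy(), traj.y[a:b].copy(), traj.fps, traj.mask[a:b].copy(), traj.time_s[a:b].copy()
    )


__all__.append("slice_trajectory")
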