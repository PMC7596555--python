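"""ConceFT time-frequency analysis and the 28 spectral pursuit features.

ConceFT ("concentration of frequency and time") is a multitaper extension of
the synchrosqueezing transform (SST).  A short-time transform is computed with
an orthonormal family of Hermite windows; for each of many random unit-norm
complex combinations of those windows an SST is formed by reassigning each
coefficient to its estimated instantaneous frequency, and the squeezed power
of all combinations is averaged.  The result is a sharply concentrated
time-frequency representation that is far less noisy than a single-taper SST.

From the representation of one pursuit trial the feature extractor divides
the 1-8 Hz range into 14 half-Hz bands and computes per band the sum and the
variance of power, each normalized by the corresponding total across bands:
14 "Sum" + 14 "Var" = 28 features per trial.  Saccadic pursuit concentrates
power around 1.5-2.5 Hz (the typical catch-up saccade rhythm), which these
features capture.

Frames whose analysis window overlaps blink-interpolated or missing samples
are excluded from all feature computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateSignalError,
    EmptySignalError,
    InvalidParameterError,
)
from .trajectory import GazeTrajectory, Mask

__all__ = [
    "TFRepresentation",
    "ConceFTFeatures",
    "BAND_EDGES",
    "default_freq_grid",
    "hermite_windows",
    "sst",
    "conceft_transform",
    "conceft_of_trajectory",
    "extract_features",
    "average_trials",
    "band_power_fraction",
    "relative_power_spectrum",
]

#: 14 half-Hz analysis bands: 1-1.5, 1.5-2, ..., 7.5-8 Hz
BAND_EDGES = tuple((1.0 + 0.5 * k, 1.5 + 0.5 * k) for k in range(14))


def default_freq_grid(lo: float = 0.1, hi: float = 8.0, step: float = 0.05) -> np.ndarray:
    """Frequency grid in Hz, 0.05 Hz resolution by default (159 bins)."""
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


@dataclass
class TFRepresentation:
    """Time-frequency power matrix with its grids and frame validity mask."""

    power: np.ndarray  # (n_freq, n_frames), nonnegative
    freq_bins_hz: np.ndarray
    frame_times_s: np.ndarray
    frame_mask: np.ndarray  # bool, True = frame usable for features

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freq_bins_hz), len(self.frame_times_s)):
            raise InvalidParameterError("power shape must be (n_freq, n_frames)")


@dataclass
class ConceFTFeatures:
    """The 28 normalized spectral features of one trial (or trial average)."""

    sum_norm: np.ndarray  # 14 values, sums to 1
    var_norm: np.ndarray  # 14 values, sums to 1
    trial_id: str = "T1"
    band_edges: tuple = field(default=BAND_EDGES)

    def vector(self) -> np.ndarray:
        """Concatenated 28-vector: 14 Sum features then 14 Var features."""
        return np.concatenate([self.sum_norm, self.var_norm])


def hermite_windows(
    n_windows: int, length: int, half_time_bandwidth: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """First ``n_windows`` Hermite functions sampled on an odd-length support.

    Returns ``(windows, dwindows)`` of shape (length, n_windows): the sampled
    orthonormal windows and their derivatives with respect to the *sample
    index* (multiply by the sampling rate for derivatives in seconds).  The
    sampled family is re-orthonormalized by QR so discrete inner products are
    exactly the identity; derivatives get the same change of basis.
    """
    if n_windows < 1:
        raise InvalidParameterError("n_windows must be >= 1")
    if length % 2 == 0:
        raise InvalidParameterError("window length must be odd")
    if n_windows > length:
        raise InvalidParameterError("n_windows cannot exceed window length")

    t = np.linspace(-half_time_bandwidth, half_time_bandwidth, length)
    dt = t[1] - t[0]
    k_max = n_windows  # one extra order for the derivative recurrence
    psi = np.empty((length, k_max + 1))
    psi[:, 0] = np.pi ** (-0.25) * np.exp(-(t**2) / 2.0)
    if k_max >= 1:
        psi[:, 1] = np.sqrt(2.0) * t * psi[:, 0]
    for k in range(2, k_max + 1):
        psi[:, k] = np.sqrt(2.0 / k) * t * psi[:, k - 1] - np.sqrt((k - 1) / k) * psi[:, k - 2]

    # analytic derivative in support units: psi_k' = sqrt(k/2) psi_{k-1} - sqrt((k+1)/2) psi_{k+1}
    dpsi = np.empty((length, k_max))
    for k in range(k_max):
        lower = np.sqrt(k / 2.0) * psi[:, k - 1] if k >= 1 else 0.0
        dpsi[:, k] = lower - np.sqrt((k + 1) / 2.0) * psi[:, k + 1]

    raw = psi[:, :n_windows]
    q, r = np.linalg.qr(raw)
    sign = np.sign(np.diag(r))
    sign[sign == 0] = 1.0
    q = q * sign
    r = r * sign[:, None]
    dq = dpsi[:, :n_windows] @ np.linalg.inv(r)
    # derivative w.r.t. sample index = derivative in support units * dt
    return q, dq * dt


def _stft_pair(
    x: np.ndarray,
    window: np.ndarray,
    dwindow: np.ndarray,
    fs: float,
    freq_grid: np.ndarray,
    hop: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time transforms of x with a window and its time derivative.

    Returns (V, Vd, centers): complex matrices of shape (n_frames, n_freq)
    and the sample index of each frame center.  Frames are centered on every
    ``hop``-th sample; the signal is zero-padded at the edges.
    """
    L = len(window)
    half = L // 2
    n = len(x)
    xp = np.concatenate([np.zeros(half), x, np.zeros(half)])
    centers = np.arange(0, n, hop)
    frames = np.lib.stride_tricks.sliding_window_view(xp, L)[centers]  # (n_frames, L)
    m = np.arange(L) - half
    phase = np.exp(-2j * np.pi * np.outer(m / fs, freq_grid))  # (L, n_freq)
    V = (frames * window) @ phase
    Vd = (frames * (dwindow * fs)) @ phase
    return V, Vd, centers


def sst(
    signal: np.ndarray,
    fs: float,
    window: np.ndarray | None = None,
    dwindow: np.ndarray | None = None,
    freq_grid: np.ndarray | None = None,
    squeeze_threshold: float = 1e-8,
    hop: int = 1,
) -> TFRepresentation:
    """Synchrosqueezing transform of a gapless real signal.

    Coefficients of the windowed short-time transform are reassigned along
    frequency to the instantaneous-frequency estimate
    ``f - Im(V_g' / V_g) / (2 pi)``; their squared magnitudes accumulate in
    the nearest grid bin.  Coefficients below ``squeeze_threshold`` times the
    maximum magnitude are discarded.
    """
    x = np.asarray(signal, float)
    if len(x) == 0:
        raise EmptySignalError("empty signal")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("signal must be finite (interpolate gaps first)")
    if freq_grid is None:
        freq_grid = default_freq_grid()
    if freq_grid[-1] > fs / 2:
        raise InvalidParameterError("frequency grid exceeds Nyquist")
    if window is None or dwindow is None:
        L = min(len(x) // 2 * 2 - 1, int(round(2.0 * fs)) | 1)
        W, dW = hermite_windows(1, L)
        window, dwindow = W[:, 0], dW[:, 0]

    V, Vd, centers = _stft_pair(x, window, dwindow, fs, freq_grid, hop)
    power = _squeeze(V, Vd, freq_grid, squeeze_threshold)
    times = centers / fs
    mask = np.ones(len(centers), bool)
    return TFRepresentation(power, np.asarray(freq_grid, float), times, mask)


def _squeeze(
    V: np.ndarray, Vd: np.ndarray, freq_grid: np.ndarray, squeeze_threshold: float
) -> np.ndarray:
    """Reassign |V|^2 into frequency bins of the grid; returns (n_freq, n_frames)."""
    n_frames, n_freq = V.shape
    mag = np.abs(V)
    thr = squeeze_threshold * mag.max() if mag.max() > 0 else np.inf
    keep = mag > thr
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = freq_grid[None, :] - np.imag(Vd / V) / (2 * np.pi)
    finite = np.isfinite(omega)
    omega = np.where(finite, omega, -1.0)
    step = freq_grid[1] - freq_grid[0]
    bins = np.round((omega - freq_grid[0]) / step).astype(np.int64)
    in_range = (bins >= 0) & (bins < n_freq) & keep & finite
    power = np.zeros((n_freq, n_frames))
    fr_idx = np.broadcast_to(np.arange(n_frames)[:, None], V.shape)
    flat = bins[in_range] * n_frames + fr_idx[in_range]
    np.add.at(power.ravel(), flat, mag[in_range] ** 2)
    return power


def conceft_transform(
    signal: np.ndarray,
    fs: float,
    n_windows: int = 2,
    n_projections: int = 30,
    freq_grid: np.ndarray | None = None,
    seed: int = 0,
    window_s: float = 2.0,
    hop: int = 1,
    half_time_bandwidth: float = 6.0,
    squeeze_threshold: float = 1e-8,
    sample_mask: np.ndarray | None = None,
) -> TFRepresentation:
    """Multitaper synchrosqueezed transform averaged over random projections.

    Each projection draws a random unit-norm complex combination of the
    orthonormal Hermite windows, squeezes the resulting STFT, and the squeezed
    powers are averaged.  Deterministic given ``seed``.

    ``sample_mask`` (per-sample, ``Mask`` codes or bool non-valid) marks
    samples whose content is synthetic (blink-interpolated/missing); any
    output frame whose window support overlaps such a sample is flagged
    invalid in ``frame_mask``.
    """
    x = np.asarray(signal, float)
    if len(x) == 0:
        raise EmptySignalError("empty signal")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("signal must be finite (interpolate gaps first)")
    if n_projections < 1:
        raise InvalidParameterError("n_projections must be >= 1")
    if freq_grid is None:
        freq_grid = default_freq_grid()
    freq_grid = np.asarray(freq_grid, float)
    if freq_grid[-1] > fs / 2:
        raise InvalidParameterError("frequency grid exceeds Nyquist")

    L = int(round(window_s * fs))
    if L % 2 == 0:
        L += 1
    L = min(L, len(x) if len(x) % 2 == 1 else len(x) - 1)
    W, dW = hermite_windows(n_windows, L, half_time_bandwidth)

    Vs, Vds = [], []
    centers = None
    for k in range(n_windows):
        V, Vd, centers = _stft_pair(x, W[:, k], dW[:, k], fs, freq_grid, hop)
        Vs.append(V)
        Vds.append(Vd)
    Vs = np.stack(Vs)  # (K, n_frames, n_freq)
    Vds = np.stack(Vds)

    rng = np.random.default_rng(seed)
    acc = np.zeros((len(freq_grid), len(centers)))
    for _ in range(n_projections):
        c = rng.normal(size=n_windows) + 1j * rng.normal(size=n_windows)
        c /= np.linalg.norm(c)
        V = np.tensordot(c, Vs, axes=1)
        Vd = np.tensordot(c, Vds, axes=1)
        acc += _squeeze(V, Vd, freq_grid, squeeze_threshold)
    acc /= n_projections

    times = centers / fs
    if sample_mask is not None:
        bad = np.asarray(sample_mask) != Mask.VALID
        # a frame is unusable if a synthetic sample lies where the Hermite
        # windows have non-negligible amplitude; beyond ~0.65 of the support
        # the tapers have decayed below 1e-3, so leakage there is irrelevant
        half = L // 2
        radius = int(np.ceil(0.65 * half))
        cum = np.concatenate([[0], np.cumsum(bad.astype(np.int64))])
        lo = np.clip(centers - radius, 0, len(x))
        hi = np.clip(centers + radius + 1, 0, len(x))
        frame_mask = (cum[hi] - cum[lo]) == 0
    else:
        frame_mask = np.ones(len(centers), bool)
    return TFRepresentation(acc, freq_grid, times, frame_mask)


def conceft_of_trajectory(
    traj: GazeTrajectory,
    n_windows: int = 2,
    n_projections: int = 30,
    freq_grid: np.ndarray | None = None,
    seed: int = 0,
    window_s: float = 2.0,
    hop: int = 1,
    squeeze_threshold: float = 1e-8,
) -> TFRepresentation:
    """ConceFT of the horizontal NIC channel, honoring the trajectory mask."""
    return conceft_transform(
        traj.x,
        traj.fps,
        n_windows=n_windows,
        n_projections=n_projections,
        freq_grid=freq_grid,
        seed=seed,
        window_s=window_s,
        hop=hop,
        squeeze_threshold=squeeze_threshold,
        sample_mask=traj.mask,
    )


def _band_bins(freq: np.ndarray, lo: float, hi: float, closed_right: bool = False) -> np.ndarray:
    if closed_right:
        return (freq >= lo - 1e-9) & (freq <= hi + 1e-9)
    return (freq >= lo - 1e-9) & (freq < hi - 1e-9)


def extract_features(tfr: TFRepresentation, trial_id: str = "T1") -> ConceFTFeatures:
    """The 28 normalized band features of a time-frequency representation.

    Per half-Hz band between 1 and 8 Hz, the sum and the variance of the
    power values over (band bins x valid frames) are computed; sums are
    normalized by the total sum, variances by the total variance.  Masked
    frames are excluded entirely.
    """
    valid = tfr.frame_mask
    if not valid.any():
        raise EmptySignalError("no valid time frames to extract features from")
    P = tfr.power[:, valid]
    sums = np.empty(14)
    vars_ = np.empty(14)
    for b, (lo, hi) in enumerate(BAND_EDGES):
        bins = _band_bins(tfr.freq_bins_hz, lo, hi, closed_right=(b == 13))
        block = P[bins]
        if block.size == 0:
            raise InvalidParameterError(f"frequency grid does not cover band {lo}-{hi} Hz")
        sums[b] = block.sum()
        vars_[b] = block.var()
    tot_s, tot_v = sums.sum(), vars_.sum()
    if tot_s <= 0 or tot_v <= 0:
        raise DegenerateSignalError("zero spectral power in the 1-8 Hz range")
    return ConceFTFeatures(sums / tot_s, vars_ / tot_v, trial_id)


def average_trials(f_t1: ConceFTFeatures, f_t2: ConceFTFeatures) -> ConceFTFeatures:
    """Element-wise mean of two trials' feature vectors."""
    if f_t1.band_edges != f_t2.band_edges:
        raise InvalidParameterError("band definitions differ between trials")
    return ConceFTFeatures(
        (f_t1.sum_norm + f_t2.sum_norm) / 2.0,
        (f_t1.var_norm + f_t2.var_norm) / 2.0,
        trial_id=f"{f_t1.trial_id}+{f_t2.trial_id}",
        band_edges=f_t1.band_edges,
    )


def band_power_fraction(
    tfr: TFRepresentation,
    lo_hz: float = 1.5,
    hi_hz: float = 2.5,
    total_lo_hz: float = 0.1,
    total_hi_hz: float = 8.0,
) -> float:
    """Fraction of valid-frame power in [lo, hi) relative to the whole range."""
    if not lo_hz < hi_hz:
        raise InvalidParameterError("need lo_hz < hi_hz")
    valid = tfr.frame_mask
    if not valid.any():
        raise EmptySignalError("no valid time frames")
    P = tfr.power[:, valid]
    total = P[_band_bins(tfr.freq_bins_hz, total_lo_hz, total_hi_hz, closed_right=True)].sum()
    if total <= 0:
        raise DegenerateSignalError("zero total spectral power")
    closed = hi_hz >= total_hi_hz - 1e-9
    band = P[_band_bins(tfr.freq_bins_hz, lo_hz, hi_hz, closed_right=closed)].sum()
    return float(band / total)


def relative_power_spectrum(tfr: TFRepresentation) -> np.ndarray:
    """Per-bin power over valid frames, normalized to sum to 1 across the grid."""
    valid = tfr.frame_mask
    if not valid.any():
        raise EmptySignalError("no valid time frames")
    p = tfr.power[:, valid].sum(axis=1)
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("zero total spectral power")
    return p / total
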