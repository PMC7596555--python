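"""Pipeline configuration with the package defaults, loadable from TOML."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the trajectory -> spectral-feature pipeline.

    Defaults are the package's analysis conditions: left-eye channel, scaled
    NIC, EAR blink threshold 0.2 with 3-frame padding, 8 Hz zero-phase
    low-pass, decimation to 60 Hz for the spectral stage, 1 s repeated-median
    detrend window, ConceFT with 2 Hermite tapers and 30 random projections
    on a 0.05 Hz grid over 0.1-8 Hz.
    """

    eye: str = "left"
    nic_scaling: bool = True
    ear_threshold: float = 0.2
    blink_pad_frames: int = 3
    lowpass_cutoff_hz: float = 8.0
    lowpass_order: int = 4
    analysis_rate_hz: float = 60.0  # decimation target for the spectral stage
    detrend_window_s: float = 1.0
    conceft_n_windows: int = 2
    conceft_n_projections: int = 30
    conceft_window_s: float = 2.0
    conceft_hop: int = 5
    freq_grid_lo_hz: float = 0.1
    freq_grid_hi_hz: float = 8.0
    freq_grid_step_hz: float = 0.05
    squeeze_threshold: float = 1e-8
    band_lo_hz: float = 1.5
    band_hi_hz: float = 2.5
    include_pause_frames: bool = True
    svm_C: float = 1.0
    classifier_standardize: str = "per_fold"
    severity_l1_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise InvalidParameterError("eye must be 'left' or 'right'")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
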