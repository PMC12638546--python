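"""Pipeline configuration: every tunable in one validated record.

Constants the method itself fixes (duration bounds, the 20% symmetry gate,
the 0.25 / 0.3 displacement levels, the 500-column matrix, the 0.2–0.7
normalization range and 0.1 s gridlines) are reported by
:func:`method_constants` and are not tunable; everything else is an
artifact choice with a config key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import blink_detect, blinkmatrix, eyelid, phases, signals, synthetic_eye

__all__ = ["PipelineConfig", "method_constants"]


@dataclass
class PipelineConfig:
    # signals
    event_threshold: float = signals.DEFAULT_EVENT_THRESHOLD
    event_downsample: int = 1
    # detection
    smooth_window: int | None = None  # None -> round(fps / 48)
    prominence_scale: float = 4.0
    baseline_return_frac: float = 0.02
    require_two_bursts: bool = True
    pad_frames: int = blink_detect.DEFAULT_PAD_FRAMES
    # eyelid estimation
    poly_degree: int = eyelid.DEFAULT_POLY_DEGREE
    fit_tol_px: float = eyelid.DEFAULT_TOL_PX
    fit_max_iter: int = eyelid.DEFAULT_MAX_ITER
    roi_margin: int = eyelid.DEFAULT_ROI_MARGIN
    per_frame_threshold: bool = False
    # phases
    center_width: int = phases.DEFAULT_CENTER_WIDTH
    reopen_frac: float = phases.DEFAULT_REOPEN_FRAC
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_threshold <= 0:
            raise ValueError("event_threshold must be > 0")
        if self.event_downsample < 1:
            raise ValueError("event_downsample must be >= 1")
        if self.smooth_window is not None and self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1 (or null for auto)")
        if self.pad_frames < 0:
            raise ValueError("pad_frames must be >= 0")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.fit_tol_px <= 0 or self.fit_max_iter < 1:
            raise ValueError("fit_tol_px must be > 0 and fit_max_iter >= 1")
        if not 0 < self.reopen_frac <= 1:
            raise ValueError("reopen_frac must lie in (0, 1]")
        if self.center_width < 1 or self.center_width > blinkmatrix.MATRIX_WIDTH:
            raise ValueError("center_width out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def method_constants() -> dict:
    """The constants the method specifies (not configurable)."""
    return {
        "min_blink_ms": blink_detect.MIN_BLINK_MS,
        "max_blink_ms": blink_detect.MAX_BLINK_MS,
        "max_asymmetry": blink_detect.MAX_ASYMMETRY,
        "complete_closed_level": synthetic_eye.COMPLETE_CLOSED_LEVEL,
        "incomplete_min_level": synthetic_eye.INCOMPLETE_MIN_LEVEL,
        "norm_range": [synthetic_eye.CLOSED_LEVEL, synthetic_eye.OPEN_LEVEL],
        "matrix_width": blinkmatrix.MATRIX_WIDTH,
        "gridline_interval_s": blinkmatrix.GRIDLINE_INTERVAL_S,
    }
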