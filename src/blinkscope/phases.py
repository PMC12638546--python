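"""Phase segmentation, pattern classification and blink parameters.

The blink matrix's center column over time is the eyelid displacement trace
(0.2–0.7 scale, larger = more open).  One blink divides into three
contiguous phases: the complete-closed phase is the contiguous interval
around the global minimum where displacement sits below 0.25 (absent when
the minimum stays above it — and a blink whose minimum never drops below
0.3 is an incomplete blink); the closing phase precedes it, the opening
phase follows.  A blink whose trace dips twice without reopening in between
is a consecutive blink.

Boundary estimation: the open↔moving boundaries are found as sub-frame
threshold crossings of a lightly smoothed trace, with a quadratic-onset
extrapolation (exact for any trajectory whose flank starts or ends with a
smooth, parabolic shoulder) so the recovered phase durations track the true
motion boundaries to within about a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .blinkmatrix import BlinkMatrix, MATRIX_WIDTH
from .synthetic_eye import (
    CLOSED_LEVEL,
    COMPLETE_CLOSED_LEVEL,
    INCOMPLETE_MIN_LEVEL,
    OPEN_LEVEL,
)

__all__ = [
    "DisplacementTrace",
    "PhaseSegmentation",
    "BlinkRecord",
    "NotABlinkError",
    "displacement_trace",
    "segment_phases",
    "classify_blink",
    "blink_parameters",
    "analyze_trace",
    "parameters_from_durations",
]

DEFAULT_CENTER_WIDTH = 10
DEFAULT_REOPEN_FRAC = 0.9
_MIN_SPAN = 0.05  # smallest descent accepted as a blink, normalized units


class NotABlinkError(ValueError):
    """The trace lacks the descent-ascent structure of a blink."""


@dataclass
class DisplacementTrace:
    """Per-frame normalized eyelid displacement (0.2–0.7, larger = open)."""

    d: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class PhaseSegmentation:
    """Half-open frame intervals of the three phases.

    ``closed`` is empty (start == stop) when no complete-closed phase
    exists, in which case ``complete`` is False.
    """

    closing: tuple[int, int]
    closed: tuple[int, int]
    opening: tuple[int, int]
    complete: bool

    def __post_init__(self) -> None:
        if not (self.closing[1] == self.closed[0] and self.closed[1] == self.opening[0]):
            raise ValueError("phases must be contiguous")
        if self.complete != (self.closed[1] > self.closed[0]):
            raise ValueError("complete must mirror a non-empty closed interval")

    @property
    def span(self) -> tuple[int, int]:
        return self.closing[0], self.opening[1]


@dataclass
class BlinkRecord:
    """One analyzed blink: trace, segmentation, label, parameter set."""

    trace: DisplacementTrace
    phases: PhaseSegmentation
    label: str
    params: dict = field(default_factory=dict)


def displacement_trace(bm: BlinkMatrix, center_width: int = DEFAULT_CENTER_WIDTH) -> DisplacementTrace:
    """Mean of the matrix's central columns, per frame."""
    lo = MATRIX_WIDTH // 2 - center_width // 2
    return DisplacementTrace(d=bm.m[:, lo:lo + center_width].mean(axis=1), fps=bm.fps)


def _smooth(d: np.ndarray) -> np.ndarray:
    if len(d) < 5:
        return d.astype(float)
    window = min(9, len(d) if len(d) % 2 else len(d) - 1)
    return savgol_filter(d, window, 2)


def _noise_sigma(d: np.ndarray, ds: np.ndarray) -> float:
    resid = d - ds
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def _cross_down(ds: np.ndarray, level: float, before: int) -> float | None:
    """Sub-frame time of the last downward crossing of ``level`` before ``before``."""
    for i in range(before - 1, 0, -1):
        if ds[i - 1] >= level > ds[i]:
            return (i - 1) + (ds[i - 1] - level) / (ds[i - 1] - ds[i])
    return None


def _cross_up(ds: np.ndarray, level: float, after: int) -> float | None:
    """Sub-frame time of the first upward crossing of ``level`` at/after ``after``."""
    for i in range(max(after, 1), len(ds)):
        if ds[i - 1] < level <= ds[i]:
            return (i - 1) + (level - ds[i - 1]) / (ds[i] - ds[i - 1])
    return None


def segment_phases(trace: DisplacementTrace) -> PhaseSegmentation:
    """Split one blink trace into closing / complete-closed / opening.

    The trace is expected to include some fully open context on both sides
    (the clip padding provides it).
    """
    d = trace.d
    n = len(d)
    if n < 3:
        raise NotABlinkError("trace too short")
    ds = _smooth(d)
    k = min(5, n)
    d_open = float(np.median(ds[:k]))
    d_end = float(np.median(ds[-k:]))
    m = int(np.argmin(ds))
    d_min = float(ds[m])
    span = d_open - d_min
    if span < _MIN_SPAN or m == 0 or m == n - 1:
        raise NotABlinkError("no descent-ascent structure in trace")
    sigma = _noise_sigma(d, ds)

    # complete-closed interval, or the first attainment of the minimum
    if d_min < COMPLETE_CLOSED_LEVEL:
        below = ds < COMPLETE_CLOSED_LEVEL
        c_lo = m
        while c_lo > 0 and below[c_lo - 1]:
            c_lo -= 1
        c_hi = m
        while c_hi + 1 < n and below[c_hi + 1]:
            c_hi += 1
        c_hi += 1
        complete = True
    else:
        # first attainment of the minimum, extrapolated through the smooth
        # (parabolic) approach the same way as the onset/end boundaries
        # crossing levels sit well above pixel quantization (~0.01 on the
        # normalized scale); the last fraction of the approach carries no
        # usable slope information
        e1 = max(4 * sigma, 0.01)

        def _attain_estimate(y: np.ndarray) -> float | None:
            ta = _cross_down(y, d_min + e1, m + 1)
            tb = _cross_down(y, d_min + 4 * e1, m + 1)
            if ta is None or tb is None or not ta > tb:
                return None
            return min(2 * ta - tb, ta + 10.0)

        holds = [t for t in (_attain_estimate(d), _attain_estimate(ds)) if t is not None]
        if holds:
            c_lo = min(int(np.floor(float(np.mean(holds)))) + 1, m)
        else:
            c_lo = m
        c_hi = c_lo
        complete = False

    # blink onset: two-level sub-frame crossing extrapolation.  For a flank
    # leaving the open level with a parabolic shoulder, excursion e is
    # reached at t0 + K sqrt(e), so t0 = 2 t(e) - t(4e); this needs no local
    # slope estimate (which pixel quantization makes unreliable).
    eps1 = max(0.02 * span, 4 * sigma)
    anchor = c_lo if c_lo > 0 else m

    def _onset_estimate(y: np.ndarray) -> float | None:
        t1 = _cross_down(y, d_open - eps1, anchor)
        if t1 is None:
            return None
        t1b = _cross_down(y, d_open - 4 * eps1, anchor) if 4 * eps1 < span else None
        t0 = 2 * t1 - t1b if t1b is not None and t1b > t1 else t1
        return max(t0, t1 - 10.0)

    # the raw (quantized) and the smoothed trace err in complementary ways
    # near the boundary; their mean is the steadiest estimate
    onsets = [t for t in (_onset_estimate(d), _onset_estimate(ds)) if t is not None]
    if not onsets:
        start = 0
    else:
        # closing begins at the first frame sampled strictly after onset
        start = max(0, int(np.floor(float(np.mean(onsets)))) + 1)
    start = min(start, max(c_lo - 1, 0))

    # blink end: mirrored on the reopening side
    span_end = d_end - d_min
    if span_end < _MIN_SPAN:
        end = n
    else:
        eps2 = max(0.02 * span_end, 4 * sigma)

        def _end_estimate(y: np.ndarray) -> float | None:
            t2 = _cross_up(y, d_end - eps2, c_hi)
            if t2 is None:
                return None
            t2a = _cross_up(y, d_end - 4 * eps2, c_hi) if 4 * eps2 < span_end else None
            t_end = 2 * t2 - t2a if t2a is not None and t2a < t2 else t2
            return min(t_end, t2 + 10.0)

        ends = [t for t in (_end_estimate(d), _end_estimate(ds)) if t is not None]
        end = min(n, int(np.floor(float(np.mean(ends)))) + 1) if ends else n
    end = max(end, c_hi + 1)

    return PhaseSegmentation(
        closing=(start, c_lo), closed=(c_lo, c_hi), opening=(c_hi, end), complete=complete
    )


def classify_blink(
    trace: DisplacementTrace,
    phases: PhaseSegmentation,
    reopen_frac: float = DEFAULT_REOPEN_FRAC,
) -> str:
    """normal / incomplete / consecutive.

    Consecutive: at least two separated dips whose intervening maximum stays
    below the reopen level ``d0 - (1 - reopen_frac) * (d0 - 0.2)`` — the lid
    started a second descent before reopening.  Incomplete: the minimum
    never falls below 0.3.  Otherwise normal (including the 0.25–0.3 band,
    where no complete-closed phase exists but closure is essentially full).
    """
    if not 0 < reopen_frac <= 1:
        raise ValueError("reopen_frac must lie in (0, 1]")
    d = trace.d
    ds = _smooth(d)
    k = min(5, len(d))
    d_open = float(np.median(ds[:k]))
    d_min = float(ds.min())
    span = d_open - d_min
    reopen_level = d_open - (1 - reopen_frac) * (d_open - CLOSED_LEVEL)
    minima, _ = find_peaks(-ds, prominence=max(0.1 * span, 0.02))
    rise_floor = max(0.1 * span, 0.02)
    if len(minima) >= 2:
        for a, b in zip(minima[:-1], minima[1:]):
            between = ds[a:b + 1].max()
            # a genuine second descent needs a real partial reopen between
            # the dips; micro-wiggles on a flat closed bottom do not qualify
            if between < reopen_level and between - max(ds[a], ds[b]) >= rise_floor:
                return "consecutive"
    if d_min > INCOMPLETE_MIN_LEVEL:
        return "incomplete"
    return "normal"


def blink_parameters(trace: DisplacementTrace, phases: PhaseSegmentation) -> dict:
    """The blink parameter set computed from trace + segmentation.

    Durations in ms; speeds in normalized units per second (None for a
    zero-length phase); displacements on the 0.2–0.7 scale.
    """
    fps = trace.fps
    d = trace.d

    def dur_ms(iv: tuple[int, int]) -> float:
        return (iv[1] - iv[0]) / fps * 1000

    closing_ms = dur_ms(phases.closing)
    closed_ms = dur_ms(phases.closed)
    opening_ms = dur_ms(phases.opening)
    total_ms = closing_ms + closed_ms + opening_ms
    min_d = float(d[phases.span[0]:phases.span[1]].min())

    closing_speed = None
    if closing_ms > 0:
        drop = float(d[phases.closing[0]] - d[phases.closing[1]])
        closing_speed = drop / (closing_ms / 1000)
    opening_speed = None
    if opening_ms > 0:
        last = min(phases.opening[1], len(d) - 1)
        rise = float(d[last] - d[phases.opening[0]])
        opening_speed = rise / (opening_ms / 1000)

    return {
        "total_duration_ms": total_ms,
        "closing_ms": closing_ms,
        "closed_ms": closed_ms,
        "opening_ms": opening_ms,
        "closed_ratio_pct": (closed_ms / total_ms * 100) if total_ms > 0 else 0.0,
        "closing_speed": closing_speed,
        "opening_speed": opening_speed,
        "total_displacement": float(d[0]) - min_d,
        "min_displacement": min_d,
    }


def analyze_trace(trace: DisplacementTrace, reopen_frac: float = DEFAULT_REOPEN_FRAC) -> BlinkRecord:
    """Segment, classify and parameterize one displacement trace."""
    phases = segment_phases(trace)
    label = classify_blink(trace, phases, reopen_frac=reopen_frac)
    params = blink_parameters(trace, phases)
    return BlinkRecord(trace=trace, phases=phases, label=label, params=params)


def parameters_from_durations(
    closing_ms: float,
    closed_ms: float,
    opening_ms: float,
    initial_displacement: float = OPEN_LEVEL,
    min_displacement: float | None = None,
) -> dict:
    """Parameter arithmetic from stated phase durations (no trace needed).

    Useful for checking reported values: total duration, the closed-phase
    ratio, and — when a minimum displacement is given — the total eyelid
    excursion.
    """
    total = closing_ms + closed_ms + opening_ms
    out = {
        "total_duration_ms": total,
        "closed_ratio_pct": closed_ms / total * 100 if total > 0 else 0.0,
    }
    if min_displacement is not None:
        out["total_displacement"] = initial_displacement - min_displacement
    return out
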