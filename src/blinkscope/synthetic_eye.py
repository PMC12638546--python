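"""Synthetic eye-blink video generator with exact ground truth.

Renders a schematic eye region — bright skin, a dark eye bounded above by a
downward-opening quadratic arch (the upper-eyelid margin) — whose apex
descends and rises along a configurable trajectory.  Every downstream stage
of the pipeline is tested against the ground truth this module emits.

Phase-duration semantics
------------------------
A blink's ``close_ms / closed_ms / open_ms`` are the durations of the three
blink phases *as the displacement rule defines them*: the complete-closed
phase is where the normalized displacement (0.2–0.7 scale, 0.7 = open) sits
below 0.25, the closing phase precedes it and the opening phase follows it.
For a complete blink (amplitude > 0.9, so the hold level is below 0.25) the
generator solves the internal segment lengths in closed form so that the
requested rule durations are realized exactly:

* closing flank: quarter-cosine, ``x(u) = 1 - cos(pi u / 2)`` — a smooth
  shoulder at the open end and a contact stop at the closed end (the upper
  lid arrests on the lower lid);
* hold at full closure;
* opening flank: ``x(u) = 1 - sin(pi u / 2)`` — fast release off the lower
  lid, smooth arrival at the open level.

Incomplete blinks (amplitude <= 0.9) reverse smoothly without lid contact,
so both flanks are full raised-cosine segments and the requested durations
are the flank lengths themselves; their opening phase, by the rule, runs
from the first attainment of the minimum to the end of motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .video_io import FrameSequence

__all__ = [
    "BlinkSpec",
    "SceneSpec",
    "GroundTruth",
    "GtEvent",
    "render_blink_video",
    "standard_fixtures",
    "COMPLETE_CLOSED_LEVEL",
    "INCOMPLETE_MIN_LEVEL",
    "OPEN_LEVEL",
    "CLOSED_LEVEL",
]

# Normalized displacement scale: first-frame eyelid extent maps onto
# [CLOSED_LEVEL, OPEN_LEVEL]; complete closure requires d < 0.25 and a blink
# whose minimum stays above 0.3 is incomplete.
OPEN_LEVEL = 0.7
CLOSED_LEVEL = 0.2
COMPLETE_CLOSED_LEVEL = 0.25
INCOMPLETE_MIN_LEVEL = 0.3

# amplitude above which the hold level lies below COMPLETE_CLOSED_LEVEL
_COMPLETE_AMP = (OPEN_LEVEL - COMPLETE_CLOSED_LEVEL) / (OPEN_LEVEL - CLOSED_LEVEL)


@dataclass(frozen=True)
class BlinkSpec:
    """One blink: phase durations (displacement-rule semantics) and amplitude.

    ``start_ms`` places the blink explicitly on the video timeline (time at
    which ``pre_open_ms`` begins); when None, blinks are laid out
    sequentially.  ``amplitude`` is the fraction of the palpebral aperture
    traversed; 1 = the upper lid reaches the lower lid.
    """

    pre_open_ms: float = 0.0
    close_ms: float = 100.0
    closed_ms: float = 0.0
    open_ms: float = 150.0
    post_open_ms: float = 0.0
    amplitude: float = 1.0
    start_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("pre_open_ms", "close_ms", "closed_ms", "open_ms", "post_open_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"amplitude must lie in (0, 1], got {self.amplitude}")
        if self.close_ms <= 0 or self.open_ms <= 0:
            raise ValueError("close_ms and open_ms must be > 0")

    @property
    def complete(self) -> bool:
        """True when the hold level lies below the complete-closed threshold."""
        return self.amplitude > _COMPLETE_AMP


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, photometry and nuisance parameters of the rendered scene."""

    width: int = 320
    height: int = 240
    skin_gray: int = 180
    eye_gray: int = 40
    aperture_px: float = 80.0
    arch_curvature: float = 0.02  # px of droop per px^2 from the apex
    noise_sd: float = 0.0
    flicker_amp: float = 0.0
    flicker_hz: float = 60.0
    seed: int = 0
    open_apex_row: float | None = None  # default: 30% of frame height
    lash_px: int = 4  # dark lid-margin band that stays visible at closure

    def __post_init__(self) -> None:
        if not self.eye_gray < self.skin_gray:
            raise ValueError("eye_gray must be darker than skin_gray")
        if not 0 < self.aperture_px < self.height:
            raise ValueError("aperture_px must lie in (0, height)")
        if self.arch_curvature <= 0:
            raise ValueError("arch_curvature must be > 0")

    @property
    def apex_row(self) -> float:
        return self.open_apex_row if self.open_apex_row is not None else 0.3 * self.height

    @property
    def half_width(self) -> float:
        """Half the eye span, chosen so the open arch extent equals the aperture.

        With ``arch_curvature * half_width**2 == aperture_px`` the first
        (open) frame's eyelid curve spans exactly one aperture vertically,
        which ties the renderer's displacement scale to the blink matrix's
        0.2–0.7 normalization.
        """
        return math.sqrt(self.aperture_px / self.arch_curvature)

    @property
    def lid_bottom_row(self) -> float:
        return self.apex_row + self.aperture_px


@dataclass(frozen=True)
class GtEvent:
    """Rule-based ground truth for one blink event on the rendered timeline."""

    start_frame: int
    end_frame: int  # exclusive
    closing_frames: int
    closed_frames: int
    opening_frames: int
    closing_ms: float
    closed_ms: float
    opening_ms: float
    min_displacement: float
    label: str  # normal | incomplete | consecutive


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside the rendered frames."""

    eyelid_y: np.ndarray  # true apex row per frame (px, float)
    displacement: np.ndarray  # true normalized displacement per frame
    phase_label: np.ndarray  # {open, closing, closed, opening} per frame
    fps: float
    events: list[GtEvent] = field(default_factory=list)


def _solve_segments(blink: BlinkSpec) -> tuple[float, float, float]:
    """Internal (flank, hold, flank) segment durations in ms.

    For complete blinks the requested rule durations are converted into
    trajectory segment lengths; infeasible combinations (a closed phase too
    short to accommodate the flank tails below 0.25) raise ValueError.
    """
    if not blink.complete:
        return blink.close_ms, blink.closed_ms, blink.open_ms
    frac = _COMPLETE_AMP / blink.amplitude  # closure fraction at d = 0.25
    u_c = (2 / math.pi) * math.acos(1 - frac)
    u_o = (2 / math.pi) * math.asin(1 - frac)
    close_total = blink.close_ms / u_c
    open_total = blink.open_ms / (1 - u_o)
    tail = (1 - u_c) * close_total + u_o * open_total
    hold = blink.closed_ms - tail
    if hold < 0:
        raise ValueError(
            f"closed_ms={blink.closed_ms:.1f} is infeasible at amplitude "
            f"{blink.amplitude}: the flanks alone spend {tail:.1f} ms below "
            f"the complete-closed level"
        )
    return close_total, hold, open_total


def _closure_fraction(blink: BlinkSpec, t_rel_ms: np.ndarray) -> np.ndarray:
    """Normalized closure progress (0 open .. 1 at this blink's deepest) vs time.

    ``t_rel_ms`` is measured from the start of the closing flank.
    """
    close_total, hold, open_total = _solve_segments(blink)
    x = np.zeros_like(t_rel_ms, dtype=float)
    in_close = (t_rel_ms > 0) & (t_rel_ms < close_total)
    u = t_rel_ms[in_close] / close_total
    if blink.complete:
        x[in_close] = 1 - np.cos(np.pi * u / 2)
    else:
        x[in_close] = np.sin(np.pi * u / 2) ** 2
    in_hold = (t_rel_ms >= close_total) & (t_rel_ms < close_total + hold)
    x[in_hold] = 1.0
    t_open = t_rel_ms - close_total - hold
    in_open = (t_open >= 0) & (t_open < open_total)
    u = t_open[in_open] / open_total
    if blink.complete:
        x[in_open] = 1 - np.sin(np.pi * u / 2)
    else:
        x[in_open] = np.cos(np.pi * u / 2) ** 2
    return x


def _blink_layout(blinks: Sequence[BlinkSpec]) -> list[tuple[float, BlinkSpec]]:
    """Closing-flank start time (ms) of each blink on the video timeline."""
    layout: list[tuple[float, BlinkSpec]] = []
    cursor = 0.0
    for blink in blinks:
        close_total, hold, open_total = _solve_segments(blink)
        start = blink.start_ms if blink.start_ms is not None else cursor
        closing_start = start + blink.pre_open_ms
        layout.append((closing_start, blink))
        cursor = closing_start + close_total + hold + open_total + blink.post_open_ms
    return layout


def _classify_true(d: np.ndarray, span_lo: int, span_hi: int) -> str:
    """Expected pattern label for the true displacement over one motion run."""
    seg = d[span_lo:span_hi]
    dmin = float(seg.min())
    depth = OPEN_LEVEL - dmin
    # count separated dips: local minima with meaningful prominence
    from scipy.signal import find_peaks

    minima, props = find_peaks(-seg, prominence=0.2 * depth)
    if len(minima) >= 2:
        reopen_level = OPEN_LEVEL - 0.1 * (OPEN_LEVEL - CLOSED_LEVEL)
        for a, b in zip(minima[:-1], minima[1:]):
            if seg[a:b + 1].max() < reopen_level:
                return "consecutive"
    if dmin > INCOMPLETE_MIN_LEVEL:
        return "incomplete"
    return "normal"


def _rule_labels(d: np.ndarray, x: np.ndarray, fps: float) -> tuple[np.ndarray, list[GtEvent]]:
    """Apply the displacement-rule segmentation to the true trace.

    Frames are labeled open/closing/closed/opening; each contiguous motion
    run (x > 0) yields one :class:`GtEvent` whose rule durations match the
    requested ones up to ms->frame rounding.
    """
    n = len(d)
    labels = np.full(n, "open", dtype="<U8")
    events: list[GtEvent] = []
    moving = x > 1e-9
    if not moving.any():
        return labels, events
    # contiguous runs of motion
    idx = np.flatnonzero(np.diff(np.concatenate(([0], moving.view(np.int8), [0]))))
    for lo, hi in zip(idx[::2], idx[1::2]):  # [lo, hi) is one motion run
        seg = d[lo:hi]
        dmin = float(seg.min())
        if dmin < COMPLETE_CLOSED_LEVEL:
            m = int(np.argmin(seg))
            below = seg < COMPLETE_CLOSED_LEVEL
            a = m
            while a > 0 and below[a - 1]:
                a -= 1
            b = m
            while b + 1 < len(seg) and below[b + 1]:
                b += 1
            c_lo, c_hi = lo + a, lo + b + 1
        else:
            m = lo + int(np.argmin(seg))  # first attainment
            c_lo = c_hi = m
        labels[lo:c_lo] = "closing"
        labels[c_lo:c_hi] = "closed"
        labels[c_hi:hi] = "opening"
        events.append(
            GtEvent(
                start_frame=int(lo),
                end_frame=int(hi),
                closing_frames=int(c_lo - lo),
                closed_frames=int(c_hi - c_lo),
                opening_frames=int(hi - c_hi),
                closing_ms=(c_lo - lo) / fps * 1000,
                closed_ms=(c_hi - c_lo) / fps * 1000,
                opening_ms=(hi - c_hi) / fps * 1000,
                min_displacement=dmin,
                label=_classify_true(d, lo, hi),
            )
        )
    return labels, events


def render_blink_video(
    blinks: Sequence[BlinkSpec],
    scene: SceneSpec = SceneSpec(),
    fps: float = 240.0,
    duration_ms: float | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a blink video and its exact ground truth.

    ``duration_ms`` overrides the video length (required when ``blinks`` is
    empty); otherwise the video spans all blinks plus their trailing holds.
    """
    layout = _blink_layout(blinks)
    if duration_ms is None:
        if not layout:
            raise ValueError("pass duration_ms to render a blink-free video")
        total_ms = 0.0
        for closing_start, blink in layout:
            c, h, o = _solve_segments(blink)
            total_ms = max(total_ms, closing_start + c + h + o + blink.post_open_ms)
    else:
        total_ms = duration_ms
    n_frames = int(math.floor(total_ms * fps / 1000 + 0.5))
    if n_frames < 1:
        raise ValueError("video would contain no frames")

    t_ms = np.arange(n_frames) / fps * 1000
    x = np.zeros(n_frames)
    for closing_start, blink in layout:
        x = np.maximum(x, blink.amplitude * _closure_fraction(blink, t_ms - closing_start))
    if x.max() > 1 + 1e-9:
        raise ValueError("combined blink amplitude would push the eyelid below the lower lid")

    apex = scene.apex_row + x * scene.aperture_px
    d = OPEN_LEVEL - (OPEN_LEVEL - CLOSED_LEVEL) * x
    labels, events = _rule_labels(d, x, fps)

    # --- rasterize ---
    rng = np.random.default_rng(scene.seed)
    h, w = scene.height, scene.width
    cx = w / 2
    cols = np.arange(w)
    offset = np.abs(cols - cx)
    active = offset <= scene.half_width
    arch_droop = scene.arch_curvature * (cols[active] - cx) ** 2
    rows = np.arange(h)[:, None]
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    t_s = t_ms / 1000
    for i in range(n_frames):
        base = np.full((h, w), float(scene.skin_gray))
        edge = apex[i] + arch_droop
        bottom = np.maximum(scene.lid_bottom_row, edge + scene.lash_px)
        mask = (rows >= edge[None, :]) & (rows <= bottom[None, :])
        sub = base[:, active]
        sub[mask] = scene.eye_gray
        base[:, active] = sub
        if scene.flicker_amp:
            base += scene.flicker_amp * math.sin(2 * math.pi * scene.flicker_hz * t_s[i])
        if scene.noise_sd:
            base += rng.normal(0.0, scene.noise_sd, size=base.shape)
        frames[i] = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, fps=fps)
    gt = GroundTruth(eyelid_y=apex, displacement=d, phase_label=labels, fps=fps, events=events)
    return seq, gt


def standard_fixtures(
    noise_sd: float = 2.0, scene: SceneSpec | None = None
) -> dict[str, tuple[FrameSequence, GroundTruth]]:
    """The four reference blink patterns, rendered deterministically.

    NORMAL
        Complete blink with rule phases 116/30/216 ms (total 362 ms).
    INCOMPLETE
        Amplitude 0.488, so the minimum displacement is 0.456; total
        duration 162.5 ms.
    PROLONGED
        Complete blink with rule phases 125/208/192 ms (total 525 ms),
        closed phase ~40% of the sequence.
    CONSECUTIVE
        A second complete blink launched 60 ms into the first (incomplete)
        blink's reopening.
    """
    base = scene if scene is not None else SceneSpec()
    fps = 240.0
    out: dict[str, tuple[FrameSequence, GroundTruth]] = {}

    out["NORMAL"] = render_blink_video(
        [BlinkSpec(pre_open_ms=700, close_ms=116, closed_ms=30, open_ms=216,
                   post_open_ms=700, amplitude=1.0)],
        replace(base, noise_sd=noise_sd, seed=11), fps,
    )
    out["INCOMPLETE"] = render_blink_video(
        [BlinkSpec(pre_open_ms=700, close_ms=70, closed_ms=0, open_ms=92.5,
                   post_open_ms=700, amplitude=0.488)],
        replace(base, noise_sd=noise_sd, seed=12), fps,
    )
    out["PROLONGED"] = render_blink_video(
        [BlinkSpec(pre_open_ms=600, close_ms=125, closed_ms=208, open_ms=192,
                   post_open_ms=600, amplitude=1.0)],
        replace(base, noise_sd=noise_sd, seed=13), fps,
    )
    out["CONSECUTIVE"] = render_blink_video(
        [
            BlinkSpec(start_ms=600, close_ms=80, closed_ms=0, open_ms=150,
                      amplitude=0.75),
            BlinkSpec(start_ms=740, close_ms=100, closed_ms=30, open_ms=200,
                      post_open_ms=700, amplitude=1.0),
        ],
        replace(base, noise_sd=noise_sd, seed=14), fps,
    )
    return out
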