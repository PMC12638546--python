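"""Blink candidate detection, filtering, clip extraction and statistics.

Candidates are found on the smoothed mean-intensity profile: each
sufficiently prominent local extremum is a blink apex x2, and walking
outward to where the profile returns near its baseline gives the blink
bounds x1, x3 (refined against the event profile, whose bursts bracket the
actual motion more tightly).  The event profile also confirms candidates:
a real blink shows two bursts — closing and opening — inside its span,
whereas global illumination changes move the intensity without firing
localized events.

Filters: a candidate shorter than 50 ms (eyelid flutter) or longer than
1500 ms (micro-sleep) is not a blink, and a rise/fall height mismatch above
20% indicates an environmental change rather than a blink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signals import EventProfile, IntensityProfile
from .video_io import FrameSequence

__all__ = [
    "BlinkCandidate",
    "BlinkClip",
    "detect_candidates",
    "filter_candidates",
    "extract_clips",
    "blink_statistics",
    "MIN_BLINK_MS",
    "MAX_BLINK_MS",
    "MAX_ASYMMETRY",
]

MIN_BLINK_MS = 50.0
MAX_BLINK_MS = 1500.0
MAX_ASYMMETRY = 0.20
DEFAULT_PAD_FRAMES = 12
_BASELINE_RETURN_FRAC = 0.02  # epsilon of the walk, as a fraction of peak excursion
_EVENT_REFINE_WINDOW = 12


@dataclass
class BlinkCandidate:
    """A (start, apex, end) triple on the intensity profile."""

    x1: int
    x2: int
    x3: int
    y1: float
    y2: float
    y3: float
    status: str = "pending"  # pending | accepted | rejected
    reject_reason: str = "none"  # none | too_short | too_long | asymmetric

    def duration_ms(self, fps: float) -> float:
        return (self.x3 - self.x1) / fps * 1000


@dataclass
class BlinkClip:
    """One blink's frames with context padding."""

    frames: FrameSequence
    source_span: tuple[int, int]  # (x1, x3) in source-frame indices
    pad: int

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a blink clip needs at least 2 frames")


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return np.asarray(x, dtype=float)
    from scipy.ndimage import uniform_filter1d

    # edge handling replicates the boundary value so the baseline is not
    # dragged toward zero at the ends
    return uniform_filter1d(np.asarray(x, dtype=float), size=w, mode="nearest")


def detect_candidates(
    intensity: IntensityProfile,
    events: EventProfile | None = None,
    smooth_window: int | None = None,
    prominence_scale: float = 4.0,
    baseline_return_frac: float = _BASELINE_RETURN_FRAC,
    require_two_bursts: bool = True,
) -> list[BlinkCandidate]:
    """Locate blink candidates, in temporal order, unfiltered.

    ``smooth_window`` defaults to ``round(fps / 48)`` (~5 frames at
    240 fps).  The prominence floor is ``prominence_scale`` times the median
    absolute deviation of the smoothed profile's first difference.  With
    ``require_two_bursts`` (and an event profile), candidates whose span
    lacks the closing + opening event bursts are dropped.
    """
    if events is not None and len(events) != len(intensity):
        raise ValueError("intensity and event profiles must have equal length")
    fps = intensity.fps
    w = smooth_window if smooth_window is not None else max(1, round(fps / 48))
    values = np.asarray(intensity.values, dtype=float)
    if len(values) < 2 * w:
        warnings.warn("profile shorter than twice the smoothing window; no detection")
        return []
    smoothed = _moving_average(values, w)
    baseline = float(np.median(smoothed))
    # blink polarity: covering a dark eye with brighter skin raises the mean
    polarity = 1.0 if smoothed.max() - baseline >= baseline - smoothed.min() else -1.0
    p = polarity * (smoothed - baseline)

    diffs = np.diff(p)
    mad_diff = float(np.median(np.abs(diffs - np.median(diffs))))
    mad_p = float(np.median(np.abs(p - np.median(p))))
    # floor: scaled first-difference MAD, but never below the profile's own
    # baseline spread (8 MAD) — rejects noise wiggles on quiet stretches
    floor = max(prominence_scale * mad_diff, 8 * mad_p, 1e-3)
    peaks, _ = find_peaks(p, prominence=floor)

    cands: list[BlinkCandidate] = []
    for x2 in peaks:
        eps = baseline_return_frac * p[x2]
        x1 = x2
        while x1 > 0 and p[x1 - 1] > eps:
            x1 -= 1
        x3 = x2
        while x3 < len(p) - 1 and p[x3 + 1] > eps:
            x3 += 1
        if events is not None:
            x1, x3 = _refine_with_events(events.counts, x1, x2, x3)
            if require_two_bursts and not _has_two_bursts(events.counts, x1, x3):
                continue
        if x1 < x2 < x3:
            cands.append(
                BlinkCandidate(
                    x1=int(x1), x2=int(x2), x3=int(x3),
                    y1=float(smoothed[x1]), y2=float(smoothed[x2]), y3=float(smoothed[x3]),
                )
            )
    return _merge_overlaps(cands)


def _refine_with_events(counts: np.ndarray, x1: int, x2: int, x3: int) -> tuple[int, int]:
    """Pull x1/x3 toward the first/last event burst near the walked span."""
    lo = max(0, x1 - _EVENT_REFINE_WINDOW)
    hi = min(len(counts), x3 + 1 + _EVENT_REFINE_WINDOW)
    seg = counts[lo:hi]
    if seg.max() == 0:
        return x1, x3
    ev_floor = max(1.0, 0.02 * float(seg.max()))
    active = np.flatnonzero(seg >= ev_floor)
    # counts[i] reflects change between frames i-1 and i, so motion starts one earlier
    first = lo + int(active[0]) - 1
    last = lo + int(active[-1])
    return min(x1, max(0, first)), max(x3, min(len(counts) - 1, last))


def _has_two_bursts(counts: np.ndarray, x1: int, x3: int) -> bool:
    seg = _moving_average(counts[x1:x3 + 1].astype(float), 3)
    if seg.max() <= 0:
        return False
    peaks, _ = find_peaks(seg, height=0.15 * seg.max(), prominence=0.15 * seg.max())
    return len(peaks) >= 2


def _merge_overlaps(cands: list[BlinkCandidate]) -> list[BlinkCandidate]:
    """Merge candidates with overlapping spans, keeping the taller apex.

    A consecutive blink yields one motion run but two intensity peaks whose
    outward walks cover the same span; it must be one event.
    """
    out: list[BlinkCandidate] = []
    for c in sorted(cands, key=lambda c: c.x1):
        if out and c.x1 <= out[-1].x3:
            prev = out[-1]
            keep, other = (prev, c) if abs(prev.y2 - prev.y1) >= abs(c.y2 - c.y1) else (c, prev)
            merged = BlinkCandidate(
                x1=min(prev.x1, c.x1), x2=keep.x2, x3=max(prev.x3, c.x3),
                y1=prev.y1 if prev.x1 <= c.x1 else c.y1,
                y2=keep.y2,
                y3=c.y3 if c.x3 >= prev.x3 else prev.y3,
            )
            out[-1] = merged
        else:
            out.append(c)
    return out


def filter_candidates(cands: list[BlinkCandidate], fps: float) -> list[BlinkCandidate]:
    """Set accept/reject status in place (and return the list).

    Rejections: duration under 50 ms (too_short) or over 1500 ms
    (too_long); rise/fall mismatch ``|rise - fall| / max(rise, fall)``
    above 20% (asymmetric).
    """
    for c in cands:
        duration = c.duration_ms(fps)
        rise = abs(c.y2 - c.y1)
        fall = abs(c.y2 - c.y3)
        denom = max(rise, fall)
        mismatch = abs(rise - fall) / denom if denom > 0 else 0.0
        if duration < MIN_BLINK_MS:
            c.status, c.reject_reason = "rejected", "too_short"
        elif duration > MAX_BLINK_MS:
            c.status, c.reject_reason = "rejected", "too_long"
        elif mismatch > MAX_ASYMMETRY:
            c.status, c.reject_reason = "rejected", "asymmetric"
        else:
            c.status, c.reject_reason = "accepted", "none"
    return cands


def extract_clips(
    seq: FrameSequence, cands: list[BlinkCandidate], pad: int = DEFAULT_PAD_FRAMES
) -> list[BlinkClip]:
    """One padded clip per accepted candidate, clamped to video bounds."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    clips = []
    for c in cands:
        if c.status != "accepted":
            continue
        start = max(0, c.x1 - pad)
        stop = min(len(seq), c.x3 + 1 + pad)
        clips.append(
            BlinkClip(frames=seq.subsequence(start, stop), source_span=(c.x1, c.x3), pad=pad)
        )
    return clips


def blink_statistics(
    cands: list[BlinkCandidate],
    video_duration_s: float,
    durations_ms: list[float] | None = None,
    labels: list[str] | None = None,
) -> dict:
    """Summary statistics over a video's accepted blinks.

    Blink rate per minute; mean and population standard deviation of blink
    duration; proportion of closure (summed blink time over total time);
    and, when labels are attached, the incomplete-blink ratio.
    """
    if video_duration_s <= 0:
        raise ValueError("video_duration_s must be > 0")
    accepted = [c for c in cands if c.status == "accepted"]
    out: dict = {
        "n_blinks": len(accepted),
        "blink_rate_per_min": len(accepted) / (video_duration_s / 60),
    }
    if durations_ms:
        arr = np.asarray(durations_ms, dtype=float)
        out["mean_duration_ms"] = float(arr.mean())
        out["sd_duration_ms"] = float(arr.std(ddof=0))
        out["closure_proportion_pct"] = float(arr.sum() / 1000 / video_duration_s * 100)
    if labels:
        out["incomplete_ratio_pct"] = 100 * sum(l == "incomplete" for l in labels) / len(labels)
    return out
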