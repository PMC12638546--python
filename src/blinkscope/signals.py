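"""Per-frame 1-D signals: mean grayscale intensity and simulated events.

Two complementary time series summarize a video for blink detection.  The
mean intensity varies as bright skin covers the dark eye region; the event
profile emulates a dynamic-vision (event-camera) sensor from conventional
frames: every pixel keeps a reference brightness and fires an event —
resetting the reference — whenever the current brightness deviates from it
by more than a threshold.  Each blink produces two event bursts (closing
and opening) separated by a quiet interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FrameSequence

__all__ = ["IntensityProfile", "EventProfile", "mean_intensity_profile", "simulate_events"]

DEFAULT_EVENT_THRESHOLD = 15.0


@dataclass
class IntensityProfile:
    """Per-frame mean pixel intensity (0–255)."""

    values: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EventProfile:
    """Per-frame count of pixels that fired a dynamic-vision event."""

    counts: np.ndarray
    threshold: float
    fps: float

    def __len__(self) -> int:
        return len(self.counts)


def mean_intensity_profile(seq: FrameSequence) -> IntensityProfile:
    """Arithmetic mean of each frame's pixels."""
    values = seq.frames.reshape(len(seq), -1).mean(axis=1)
    return IntensityProfile(values=values, fps=seq.fps)


def simulate_events(
    seq: FrameSequence, threshold: float = DEFAULT_EVENT_THRESHOLD, downsample: int = 1
) -> EventProfile:
    """Emulate event-camera output frame by frame.

    Per pixel, the reference level starts at the frame-0 value; at frame
    ``i >= 1`` a pixel fires (and resets its reference to the current value)
    when ``|current - reference| > threshold``.  ``counts[0]`` is 0 — no
    reference exists before frame 0.  ``downsample`` optionally strides the
    frames spatially before simulation (speed knob for HD input).

    The procedure is causal, deterministic, and invariant to adding a common
    constant to every frame.
    """
    if threshold <= 0:
        raise ValueError(f"event threshold must be > 0, got {threshold}")
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")
    frames = seq.frames[:, ::downsample, ::downsample].astype(np.int16)
    reference = frames[0].copy()
    counts = np.zeros(len(frames), dtype=np.int64)
    for i in range(1, len(frames)):
        fired = np.abs(frames[i] - reference) > threshold
        counts[i] = int(fired.sum())
        reference[fired] = frames[i][fired]
    return EventProfile(counts=counts, threshold=float(threshold), fps=seq.fps)
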