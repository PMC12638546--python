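"""Reading and writing frame sequences.

The whole pipeline operates on :class:`FrameSequence` — an ordered stack of
8-bit grayscale frames plus a frame rate.  Input can be a video container
(decoded through imageio when a suitable plugin is available) or a directory
of lexicographically ordered lossless image files with the frame rate given
either by a ``meta.json`` sidecar or an explicit override.

Coordinate convention: row 0 is the *top* of the image, larger row index is
lower in the image, 0-based indexing throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["FrameSequence", "load_video", "save_frames", "to_grayscale"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}
_SIDECAR_NAME = "meta.json"

# Rec.601 luma weights for color -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with timing metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``, dtype uint8.
    fps
        Frame rate in Hz (> 0).  Frame ``i`` has timestamp ``t0 + i / fps``.
    t0
        Timestamp of frame 0 in seconds.
    """

    frames: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, rows, cols) stack, got shape {self.frames.shape}"
            )
        if len(self.frames) == 0:
            raise ValueError("FrameSequence requires at least one frame")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    def timestamps(self) -> np.ndarray:
        """Per-frame timestamps in seconds."""
        return self.t0 + np.arange(len(self.frames)) / self.fps

    def subsequence(self, start: int, stop: int) -> "FrameSequence":
        """Frames ``start:stop`` as a new sequence with adjusted ``t0``."""
        if not 0 <= start < stop <= len(self.frames):
            raise IndexError(f"invalid span [{start}, {stop}) for {len(self)} frames")
        return FrameSequence(
            frames=self.frames[start:stop].copy(),
            fps=self.fps,
            t0=self.t0 + start / self.fps,
        )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert one frame to uint8 grayscale (Rec.601 luma, idempotent on gray)."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        gray = frame
    elif frame.ndim == 3 and frame.shape[2] in (3, 4):
        gray = np.rint(frame[..., :3].astype(np.float64) @ _LUMA)
    else:
        raise ValueError(f"cannot interpret frame of shape {frame.shape} as an image")
    return np.clip(gray, 0, 255).astype(np.uint8)


def _load_from_directory(path: Path, fps_override: float | None) -> FrameSequence:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise IOError(f"no image frames found in directory {path}")

    fps = fps_override
    if fps is None:
        sidecar = path / _SIDECAR_NAME
        if sidecar.exists():
            fps = float(json.loads(sidecar.read_text())["fps"])
        else:
            raise ValueError(
                f"directory input {path} requires fps_override or a "
                f"{_SIDECAR_NAME} sidecar with an 'fps' entry"
            )
    frames = [to_grayscale(iio.imread(f)) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames in {path} have mixed dimensions: {sorted(shapes)}")
    return FrameSequence(frames=np.stack(frames), fps=float(fps))


def _load_from_container(path: Path, fps_override: float | None) -> FrameSequence:
    import imageio.v3 as iio

    try:
        raw = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # plugin missing or corrupt file
        raise IOError(f"cannot read video container {path}: {exc}") from exc
    fps = fps_override or meta.get("fps")
    if not fps:
        raise ValueError(f"container {path} carries no fps metadata; pass fps_override")
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        raw = raw[None]  # single color frame
    frames = np.stack([to_grayscale(f) for f in raw])
    return FrameSequence(frames=frames, fps=float(fps))


def load_video(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Load a video container or an image-sequence directory as grayscale.

    Directories require ``fps_override`` or a ``meta.json`` sidecar written by
    :func:`save_frames`.  Color input is converted with Rec.601 luma weights.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"input path does not exist: {path}")
    if path.is_dir():
        return _load_from_directory(path, fps_override)
    return _load_from_container(path, fps_override)


def save_frames(seq: FrameSequence, path: str | Path) -> list[Path]:
    """Write a sequence as zero-padded PNG files plus a JSON fps sidecar.

    Returns the manifest of written files.  ``load_video`` on the directory
    round-trips bit-exactly.
    """
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(seq.frames) - 1)))
    written: list[Path] = []
    for i, frame in enumerate(seq.frames):
        out = path / f"frame_{i:0{width}d}.png"
        iio.imwrite(out, frame)
        written.append(out)
    sidecar = path / _SIDECAR_NAME
    sidecar.write_text(json.dumps({"fps": seq.fps, "t0": seq.t0}))
    written.append(sidecar)
    return written
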