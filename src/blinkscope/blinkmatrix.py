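"""The blink matrix: one blink rendered as a single normalized image.

Per-frame eyelid curves are conformed to a common domain (the modal defined
span), resampled to 500 columns, converted to upward-positive heights, and
affinely normalized so the first (open) frame's vertical extent spans
[0.2, 0.7].  The matrix is the substrate both for the jet-palette
visualization (3-D surface and 2-D projection with red dotted gridlines at
0.1 s intervals) and for the displacement trace the phase analysis uses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .eyelid import EyelidCurve
from .synthetic_eye import CLOSED_LEVEL, OPEN_LEVEL

__all__ = [
    "BlinkMatrix",
    "common_domain_length",
    "conform_curve",
    "build_matrix",
    "gridline_times",
    "render_projection",
    "render_surface",
    "MATRIX_WIDTH",
]

MATRIX_WIDTH = 500
GRIDLINE_INTERVAL_S = 0.1


@dataclass
class BlinkMatrix:
    """frames x 500 array of normalized eyelid heights (larger = more open).

    ``norm_params = (height_at_0.2, height_per_unit)`` maps upward-positive
    pixel heights h to normalized units via ``(h - h0) * scale + 0.2`` and
    supports the inverse mapping.
    """

    m: np.ndarray
    fps: float
    norm_params: tuple[float, float]

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 2 or self.m.shape[1] != MATRIX_WIDTH:
            raise ValueError(f"matrix must be (frames, {MATRIX_WIDTH}), got {self.m.shape}")
        if not np.isfinite(self.m).all():
            raise ValueError("matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.m.shape[0]

    def to_pixel_heights(self, values: np.ndarray) -> np.ndarray:
        """Invert the normalization back to upward-positive pixel heights."""
        h0, scale = self.norm_params
        return (np.asarray(values) - CLOSED_LEVEL) / scale + h0


def common_domain_length(curves: list[EyelidCurve]) -> int:
    """Modal defined-span length across frames; ties break to the larger."""
    if not curves:
        raise ValueError("no curves")
    lengths = []
    for c in curves:
        span = c.span
        if span is not None:
            lengths.append(span[1] - span[0])
    if not lengths:
        raise ValueError("all curves are empty")
    counts = Counter(lengths)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return int(best[0])


def conform_curve(curve: EyelidCurve, length: int) -> np.ndarray:
    """Fix a curve's defined block to ``length`` samples.

    Longer curves are center-trimmed (odd excess: one extra sample removed
    from the right); shorter curves are extended on both sides by
    evaluating the fitted polynomial (odd deficit: one extra on the right).
    """
    span = curve.span
    if span is None or span[1] - span[0] < 2:
        raise ValueError("curve needs at least 2 defined columns")
    lo, hi = span
    n = hi - lo
    if n == length:
        return curve.y[lo:hi].copy()
    if n > length:
        excess = n - length
        left = excess // 2
        return curve.y[lo + left:lo + left + length].copy()
    deficit = length - n
    left = deficit // 2
    right = deficit - left
    if curve.poly_coeffs is None:
        raise ValueError("cannot extend a curve without fitted poly_coeffs")
    cols = np.arange(lo - left, hi + right)
    out = np.polyval(curve.poly_coeffs, cols.astype(float))
    out[left:left + n] = curve.y[lo:hi]
    return out


def build_matrix(
    curves: list[EyelidCurve],
    fps: float,
    fallback_aperture_px: float | None = None,
) -> BlinkMatrix:
    """Assemble conformed, resampled, normalized curves into a BlinkMatrix.

    Rows are converted from image row-index (downward) to height (upward
    positive) and mapped affinely so the first row spans exactly
    [0.2, 0.7].  A flat first row (zero vertical extent) is degenerate; with
    ``fallback_aperture_px`` given, its center maps to 0.7 and one aperture
    to the full 0.5-unit span instead.
    """
    length = common_domain_length(curves)
    rows = np.stack([conform_curve(c, length) for c in curves])
    grid = np.linspace(0, length - 1, MATRIX_WIDTH)
    resampled = np.stack(
        [np.interp(grid, np.arange(length), r) for r in rows]
    )
    heights = -resampled  # row 0 is the image top, so height = -row
    h_min, h_max = float(heights[0].min()), float(heights[0].max())
    span_units = OPEN_LEVEL - CLOSED_LEVEL
    if h_max - h_min <= 1e-9:
        if fallback_aperture_px is None:
            raise ValueError(
                "first frame's eyelid curve has no vertical extent; pass "
                "fallback_aperture_px to normalize against the aperture"
            )
        scale = span_units / fallback_aperture_px
        h0 = h_max - (OPEN_LEVEL - CLOSED_LEVEL) / scale  # center -> 0.7
    else:
        scale = span_units / (h_max - h_min)
        h0 = h_min
    m = (heights - h0) * scale + CLOSED_LEVEL
    return BlinkMatrix(m=m, fps=fps, norm_params=(h0, scale))


def gridline_times(n_frames: int, fps: float, interval_s: float = GRIDLINE_INTERVAL_S) -> np.ndarray:
    """Times of the red dotted gridlines: every interior multiple of 0.1 s.

    Interior means strictly inside the open interval (0, duration).
    """
    duration = n_frames / fps
    times = []
    k = 1
    while k * interval_s < duration - 1e-9:
        times.append(k * interval_s)
        k += 1
    return np.asarray(times)


def render_projection(bm: BlinkMatrix, path: str, dpi: int = 120) -> str:
    """Write the 2-D projection: x = time, y = eyelid domain, jet colors.

    Red dotted vertical lines mark every interior multiple of 0.1 s.
    """
    fig, ax = plt.subplots(figsize=(6, 3))
    extent = (0, bm.n_frames / bm.fps, 0, MATRIX_WIDTH)
    ax.imshow(
        bm.m.T, aspect="auto", origin="lower", cmap="jet",
        vmin=CLOSED_LEVEL, vmax=OPEN_LEVEL, extent=extent,
    )
    for t in gridline_times(bm.n_frames, bm.fps):
        ax.axvline(t, color="red", linestyle=":", linewidth=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("eyelid domain")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def render_surface(bm: BlinkMatrix, path: str, dpi: int = 120) -> str:
    """Write the 3-D jet-colored surface view (cosmetic output)."""
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    t = np.arange(bm.n_frames) / bm.fps
    y = np.arange(MATRIX_WIDTH)
    tt, yy = np.meshgrid(t, y, indexing="ij")
    stride = max(1, MATRIX_WIDTH // 100)
    ax.plot_surface(
        tt[:, ::stride], yy[:, ::stride], bm.m[:, ::stride],
        cmap="jet", vmin=CLOSED_LEVEL, vmax=OPEN_LEVEL, linewidth=0,
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("eyelid domain")
    ax.set_zlabel("normalized height")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
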