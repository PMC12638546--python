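"""Upper-eyelid curve estimation from a blink clip.

Stage order, applied once per clip unless noted:

1. a binarization threshold from the histogram valley of the first frame;
2. an accumulated dynamic image — per-pixel count of binary changes across
   the clip — whose brightest blob localizes the eye ROI;
3. per frame: the raw upper edge (topmost dark pixel of each ROI column),
   iterative polynomial outlier removal, and interpolation of interior gaps
   from the fitted curve.

The iterative outlier removal replaces random-sampling RANSAC: fit a
polynomial to the current inliers, drop every column whose residual exceeds
``max(tol, 3 * median absolute residual)``, repeat until stable.  The inlier
set shrinks monotonically and the procedure is idempotent on its own output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .video_io import FrameSequence

__all__ = [
    "Roi",
    "EyelidCurve",
    "binarization_threshold",
    "accumulate_dynamic_image",
    "find_roi",
    "raw_upper_edge",
    "remove_outliers",
    "interpolate_eyelid",
    "estimate_clip",
]

DEFAULT_POLY_DEGREE = 2
DEFAULT_TOL_PX = 3.0
DEFAULT_MAX_ITER = 20
DEFAULT_ROI_MARGIN = 5
_BLOB_FRACTION = 0.25  # accumulation threshold relative to its maximum


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle in clip-frame pixel coordinates."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("Roi must have positive height and width")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.top:self.top + self.height, self.left:self.left + self.width]


@dataclass
class EyelidCurve:
    """Per-column eyelid row within the ROI.

    ``y`` holds NaN for missing columns; ``inlier_mask`` marks columns that
    survived outlier removal; ``poly_coeffs`` (numpy polyfit order, highest
    degree first) is set after fitting.
    """

    y: np.ndarray
    inlier_mask: np.ndarray
    poly_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.inlier_mask = np.asarray(self.inlier_mask, dtype=bool)
        if self.y.shape != self.inlier_mask.shape:
            raise ValueError("y and inlier_mask must have identical shape")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def span(self) -> tuple[int, int] | None:
        """(first, last+1) defined column, or None when all missing."""
        cols = np.flatnonzero(self.defined)
        if len(cols) == 0:
            return None
        return int(cols[0]), int(cols[-1]) + 1


def binarization_threshold(first_frame: np.ndarray, smooth_bins: int = 5) -> float:
    """Histogram-valley threshold from one frame.

    The 256-bin histogram is smoothed with a moving average and the deepest
    local minimum between the two highest peaks is returned.  A unimodal
    histogram falls back to Otsu's criterion; a constant image is degenerate.
    """
    frame = np.asarray(first_frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.min() == frame.max():
        raise ValueError("constant image: histogram has no valley to threshold at")
    hist = np.bincount(frame.astype(np.uint8).ravel(), minlength=256).astype(float)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(hist, kernel, mode="same")
    peaks, props = find_peaks(smooth, height=0)
    if len(peaks) >= 2:
        top_two = peaks[np.argsort(props["peak_heights"])[-2:]]
        lo, hi = int(top_two.min()), int(top_two.max())
        if hi - lo > 1:
            valley = lo + int(np.argmin(smooth[lo:hi + 1]))
            return float(valley)
    return float(threshold_otsu(frame))


def accumulate_dynamic_image(clip: FrameSequence, threshold: float) -> np.ndarray:
    """Per-pixel count of binary-value changes between consecutive frames."""
    if len(clip) < 2:
        raise ValueError("dynamic image needs at least 2 frames")
    binary = clip.frames < threshold  # True = dark (eye) class
    return np.abs(np.diff(binary.astype(np.int16), axis=0)).sum(axis=0)


def find_roi(acc: np.ndarray, margin: int = DEFAULT_ROI_MARGIN) -> Roi:
    """Bounding rectangle of the dominant motion blob, expanded by ``margin``.

    The accumulation image is thresholded at 25% of its maximum; among the
    8-connected components the one with the largest summed accumulation
    wins.  The rectangle is clamped to the frame bounds.
    """
    acc = np.asarray(acc)
    if acc.max() <= 0:
        raise ValueError("accumulation image is all zero: no motion to localize")
    blobs = cc_label(acc >= _BLOB_FRACTION * acc.max(), connectivity=2)
    best, best_sum = 0, -1.0
    for lab in range(1, blobs.max() + 1):
        s = float(acc[blobs == lab].sum())
        if s > best_sum:
            best, best_sum = lab, s
    rows, cols = np.nonzero(blobs == best)
    top = max(0, int(rows.min()) - margin)
    left = max(0, int(cols.min()) - margin)
    bottom = min(acc.shape[0], int(rows.max()) + 1 + margin)
    right = min(acc.shape[1], int(cols.max()) + 1 + margin)
    return Roi(top=top, left=left, height=bottom - top, width=right - left)


def raw_upper_edge(binary_roi: np.ndarray) -> EyelidCurve:
    """Topmost dark pixel of each column (NaN where a column has none)."""
    binary_roi = np.asarray(binary_roi, dtype=bool)
    has_dark = binary_roi.any(axis=0)
    first_dark = binary_roi.argmax(axis=0).astype(float)
    y = np.where(has_dark, first_dark, np.nan)
    return EyelidCurve(y=y, inlier_mask=has_dark.copy())


def _local_median_prefilter(
    cols: np.ndarray, y: np.ndarray, defined: np.ndarray, gate: float, half_window: int = 3
) -> np.ndarray:
    """Flag points within ``gate`` of the median of their defined neighbours."""
    keep = defined.copy()
    idx = np.flatnonzero(defined)
    for j, c in enumerate(idx):
        lo, hi = max(0, j - half_window), min(len(idx), j + half_window + 1)
        neighbourhood = y[idx[lo:hi]]
        if np.abs(y[c] - np.median(neighbourhood)) > gate:
            keep[c] = False
    return keep


def _deleted_residuals(x: np.ndarray, y: np.ndarray, coeffs: np.ndarray, degree: int) -> np.ndarray:
    """Leave-one-out (PRESS) absolute residuals, |e_i| / (1 - h_ii).

    Raw residuals under-state how far a high-leverage point (an outlier at
    the end of the column range) sits from the curve the *other* points
    support; dividing by ``1 - leverage`` recovers exactly the residual
    against the fit with that point deleted.
    """
    e = y - np.polyval(coeffs, x)
    X = np.vander(x, degree + 1)
    try:
        G = np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        return np.abs(e)
    h = np.clip(np.einsum("ij,jk,ik->i", X, G, X), 0.0, 1.0 - 1e-6)
    return np.abs(e / (1.0 - h))


def remove_outliers(
    curve: EyelidCurve,
    degree: int = DEFAULT_POLY_DEGREE,
    tol: float = DEFAULT_TOL_PX,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EyelidCurve:
    """Iteratively drop columns that disagree with the fitted polynomial.

    Each iteration fits a least-squares polynomial of ``degree`` to the
    current inliers and removes those with absolute residual above
    ``max(tol, 3 * median absolute residual)``; iteration stops when nothing
    is removed, fewer than ``degree + 2`` inliers would remain, or
    ``max_iter`` is reached.
    """
    cols = np.arange(len(curve.y))
    inliers = curve.defined & curve.inlier_mask
    if inliers.sum() < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} defined columns for a degree-{degree} fit, "
            f"have {int(inliers.sum())}"
        )
    # initialization: a point far from the median of its neighbours is held
    # out of the first fit (it can return through the consensus pass); this
    # keeps gross outliers from capturing the initial polynomial
    start = _local_median_prefilter(cols, curve.y, inliers, gate=5 * tol)
    if start.sum() >= degree + 2:
        inliers = start
    coeffs = None
    for _ in range(max_iter):
        coeffs = np.polyfit(cols[inliers], curve.y[inliers], degree)
        resid = _deleted_residuals(cols[inliers], curve.y[inliers], coeffs, degree)
        gate = max(tol, 3.0 * float(np.median(resid)))
        bad = resid > gate
        if not bad.any():
            # a heavy outlier fraction can inflate the median residual until
            # the gate stalls; a grossly off point (> 10 tol) is then trimmed
            # alone so the fit can recover
            if resid.max() > 10 * tol:
                bad = resid == resid.max()
            else:
                break
        keep = inliers.copy()
        keep[np.flatnonzero(inliers)[bad]] = False
        if keep.sum() < degree + 2:
            break
        inliers = keep
    else:
        coeffs = np.polyfit(cols[inliers], curve.y[inliers], degree)
    # consensus pass: with the cleaned fit in hand, the inlier set is every
    # originally-defined column that agrees with it (the trimming order can
    # discard sound points while the fit is still skewed)
    candidates = curve.defined & curve.inlier_mask
    resid = np.abs(curve.y[inliers] - np.polyval(coeffs, cols[inliers]))
    gate = max(tol, 3.0 * float(np.median(resid)))
    all_resid = np.abs(curve.y[candidates] - np.polyval(coeffs, cols[candidates]))
    final = np.zeros_like(candidates)
    final[np.flatnonzero(candidates)[all_resid <= gate]] = True
    if final.sum() >= degree + 2:
        inliers = final
        coeffs = np.polyfit(cols[inliers], curve.y[inliers], degree)
    return EyelidCurve(y=curve.y.copy(), inlier_mask=inliers, poly_coeffs=coeffs)


def interpolate_eyelid(curve: EyelidCurve) -> EyelidCurve:
    """Fill interior missing/outlier columns from the fitted polynomial.

    Columns outside the inlier span stay missing; the blink-matrix
    conformance step handles them.
    """
    inl = np.flatnonzero(curve.inlier_mask & curve.defined)
    if len(inl) < 2:
        raise ValueError("need at least 2 inlier columns to interpolate")
    if curve.poly_coeffs is None:
        raise ValueError("run remove_outliers first: poly_coeffs is unset")
    lo, hi = int(inl[0]), int(inl[-1]) + 1
    y = np.full_like(curve.y, np.nan)
    mask = np.zeros_like(curve.inlier_mask)
    y[inl] = curve.y[inl]
    mask[inl] = True
    fill = np.ones(len(y), dtype=bool)
    fill[inl] = False
    fill[:lo] = False
    fill[hi:] = False
    y[fill] = np.polyval(curve.poly_coeffs, np.flatnonzero(fill))
    return EyelidCurve(y=y, inlier_mask=mask, poly_coeffs=curve.poly_coeffs)


@dataclass
class ClipEyelids:
    """Per-frame interpolated eyelid curves plus the shared ROI/threshold."""

    curves: list[EyelidCurve]
    roi: Roi
    threshold: float


def estimate_clip(
    clip: FrameSequence,
    degree: int = DEFAULT_POLY_DEGREE,
    tol: float = DEFAULT_TOL_PX,
    max_iter: int = DEFAULT_MAX_ITER,
    margin: int = DEFAULT_ROI_MARGIN,
    per_frame_threshold: bool = False,
) -> ClipEyelids:
    """Run the full eyelid-estimation chain on one blink clip.

    The binarization threshold comes from the clip's first frame (or per
    frame when ``per_frame_threshold``, for flicker-heavy input) and the ROI
    from the clip-wide dynamic image.
    """
    thr = binarization_threshold(clip.frames[0])
    acc = accumulate_dynamic_image(clip, thr)
    roi = find_roi(acc, margin=margin)
    curves: list[EyelidCurve] = []
    for frame in clip.frames:
        f_thr = binarization_threshold(frame) if per_frame_threshold else thr
        binary = roi.crop(frame) < f_thr
        raw = raw_upper_edge(binary)
        fitted = remove_outliers(raw, degree=degree, tol=tol, max_iter=max_iter)
        curves.append(interpolate_eyelid(fitted))
    return ClipEyelids(curves=curves, roi=roi, threshold=thr)
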