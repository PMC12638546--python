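"""Independent reference implementations used as test oracles.

These deliberately re-derive results by brute force, separate from the
library's code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_events(trace, threshold) -> list[int]:
    """Scalar reference for the per-pixel event rule: compare to a stored
    reference level, fire and reset when the difference exceeds threshold."""
    ref = trace[0]
    fired = [0]
    for v in trace[1:]:
        if abs(int(v) - int(ref)) > threshold:
            fired.append(1)
            ref = v
        else:
            fired.append(0)
    return fired


def ransac_consensus(y: np.ndarray, degree: int = 2, tol: float = 3.0) -> np.ndarray:
    """Exhaustive-sampling RANSAC: fit every minimal sample, keep the
    largest consensus, refit, and return the final inlier mask."""
    x = np.arange(len(y), dtype=float)
    best = None
    for sample in combinations(range(len(y)), degree + 1):
        c = np.polyfit(x[list(sample)], y[list(sample)], degree)
        inliers = np.abs(y - np.polyval(c, x)) <= tol
        if best is None or inliers.sum() > best.sum():
            best = inliers
    c = np.polyfit(x[best], y[best], degree)
    return np.abs(y - np.polyval(c, x)) <= tol
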