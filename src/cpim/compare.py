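"""Rotation-minimized Hamming comparison of binary patterns.

Two binarized patterns are compared by the fraction of pixel positions
at which they differ.  Because a simulated population has no preferred
orientation relative to an observed colony, the candidate pattern is
rotated in 15-degree steps (24 versions over the full circle) and the
smallest distance is reported.  Patterns of unequal size are first
rescaled (nearest neighbour) to a common shape; rescaling precedes
rotation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _as_binary(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if not np.all(np.isin(a, (0, 1))):
        raise ValueError("pattern values must be 0/1")
    return a.astype(np.uint8)


def rescale_binary(pattern: np.ndarray,
                   target_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling to ``target_shape``; output binary."""
    p = _as_binary(pattern)
    H, W = p.shape
    th, tw = target_shape
    if th < 2 or tw < 2:
        raise ValueError("target dimensions must be >= 2")
    if (th, tw) == (H, W):
        return p.copy()
    rows = np.floor(np.arange(th) * H / th).astype(int)
    cols = np.floor(np.arange(tw) * W / tw).astype(int)
    return p[np.ix_(rows, cols)]


def rotate_binary(pattern: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate about the centre, nearest-neighbour, background fill 0.

    Output has the same shape as the input; content rotated out of
    frame is lost, uncovered corners are filled with 0.
    """
    p = _as_binary(pattern)
    angle = angle_degrees % 360
    if angle == 0:
        return p.copy()
    if angle % 90 == 0:
        return np.rot90(p, k=int(angle // 90)).copy()
    out = ndimage.rotate(p, angle, reshape=False, order=0, mode="constant",
                         cval=0, prefilter=False)
    return out.astype(np.uint8)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pixel positions at which two patterns differ."""
    a = _as_binary(a)
    b = _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}; "
                         "rescale first")
    return float(np.mean(a != b))


def min_hamming_over_rotations(a: np.ndarray, b: np.ndarray,
                               step: float = 15.0
                               ) -> tuple[float, float]:
    """Minimum Hamming distance over rotated versions of ``b``.

    Returns (min distance, argmin angle in degrees).  The default
    15-degree step generates 24 candidate orientations.
    """
    a = _as_binary(a)
    b = _as_binary(b)
    if a.shape != b.shape:
        raise ValueError("patterns must have equal shapes; rescale first")
    best = (np.inf, 0.0)
    angle = 0.0
    while angle < 360:
        d = hamming_distance(a, rotate_binary(b, angle))
        if d < best[0]:
            best = (d, angle)
        angle += step
    return best
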