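"""Mask-overlap and contour-distance scores."""

from __future__ import annotations

import numpy as np
from skimage.metrics import hausdorff_distance as _hausdorff

__all__ = ["dice", "hausdorff"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)``; 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Hausdorff distance between mask boundaries, in pixels."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        return np.inf
    return float(_hausdorff(a, b))
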