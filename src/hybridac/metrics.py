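"""Segmentation overlap metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import hausdorff_distance as _sk_hausdorff

__all__ = ["SegScore", "dice", "jaccard", "hausdorff", "changed_pixels", "seg_score"]


@dataclass(frozen=True)
class SegScore:
    dice: float
    jaccard: float
    hausdorff: float
    changed_pixels: int

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "hausdorff": self.hausdorff,
            "changed_pixels": self.changed_pixels,
        }


def _check(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    a, b = _check(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    a, b = _check(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels.

    Infinite if exactly one mask is empty; 0 if both are.
    """
    a, b = _check(a, b)
    if not a.any() and not b.any():
        return 0.0
    if not a.any() or not b.any():
        return float("inf")
    return float(_sk_hausdorff(a, b))


def changed_pixels(a, b) -> int:
    """Number of pixels whose label differs between the two masks."""
    a, b = _check(a, b)
    return int((a != b).sum())


def seg_score(pred, reference) -> SegScore:
    """All metrics of ``pred`` against ``reference`` at once."""
    return SegScore(
        dice=dice(pred, reference),
        jaccard=jaccard(pred, reference),
        hausdorff=hausdorff(pred, reference),
        changed_pixels=changed_pixels(pred, reference),
    )
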