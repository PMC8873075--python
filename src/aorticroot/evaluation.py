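"""Evaluation metrics: intersection over ground truth, F1/Dice, sizing agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rootmetry import DEVICE_SIZES_MM
from .volume_io import BoundingBoxMM, Mask

__all__ = ["SizingAgreement", "iog", "f1", "sizing_agreement"]


def iog(pred_box: BoundingBoxMM, ref_box: BoundingBoxMM) -> float:
    """Intersection over ground truth for axis-aligned boxes:
    |pred ∩ ref| / |ref|, computed analytically in mm^3.

    Applied to the postprocessed fixed-size ROI box, not to the raw
    probability map.
    """
    if ref_box.volume_mm3() <= 0:
        raise ValueError("reference box has zero volume")
    lo = np.maximum(pred_box.low_mm, ref_box.low_mm)
    hi = np.minimum(pred_box.high_mm, ref_box.high_mm)
    edges = np.clip(hi - lo, 0.0, None)
    return float(np.prod(edges) / ref_box.volume_mm3())


def f1(pred: Mask | np.ndarray, ref: Mask | np.ndarray) -> float:
    """F1 score (Dice): 2·precision·recall / (precision + recall).

    Equals 2|A∩B| / (|A| + |B|); two empty masks score 1.0 by convention.
    """
    a = (pred.values if isinstance(pred, Mask) else np.asarray(pred)) > 0
    b = (ref.values if isinstance(ref, Mask) else np.asarray(ref)) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


_STEP_LABELS = (
    "3+ sizes smaller",
    "2 sizes smaller",
    "1 size smaller",
    "correct size",
    "1 size bigger",
    "2 sizes bigger",
    "3+ sizes bigger",
)


@dataclass
class SizingAgreement:
    """Histogram of ladder-step differences (suggested minus actual) in percent."""

    counts: dict
    percentages: dict
    percent_correct: float
    n: int

    def __str__(self):
        rows = [f"{k:>18}: {self.percentages[k]:5.1f}%" for k in _STEP_LABELS]
        return "\n".join(rows)


def sizing_agreement(suggested, actual) -> SizingAgreement:
    """Tabulate suggested-vs-actual device sizes as ladder-step differences.

    Sizes must come from the device ladder 20/23/26/29/34 mm; the difference
    is counted in ladder steps and clamped into the 3-or-more bins.
    """
    suggested = list(suggested)
    actual = list(actual)
    if len(suggested) != len(actual) or not suggested:
        raise ValueError("need equal-length non-empty size lists")
    ladder = {s: i for i, s in enumerate(DEVICE_SIZES_MM)}
    counts = {k: 0 for k in _STEP_LABELS}
    for s, a in zip(suggested, actual):
        if s not in ladder or a not in ladder:
            raise ValueError(f"size not on the device ladder: {s if s not in ladder else a}")
        d = int(np.clip(ladder[s] - ladder[a], -3, 3))
        counts[_STEP_LABELS[d + 3]] += 1
    n = len(suggested)
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return SizingAgreement(
        counts=counts,
        percentages=pct,
        percent_correct=pct["correct size"],
        n=n,
    )
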