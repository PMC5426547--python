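"""Pixel-level detection scoring and 3-D position-error statistics.

Detection performance is scored against a labelled ground-truth mask inside
an evaluation ROI (by default the same region the segmentation masks allowed
detection to mark):

    TP rate    = 100 * tp / (tp + fp)        (precision of vein labelling)
    Accuracy   = 100 * (tp + tn) / total
    Error rate = 100 * (fp + fn) / total

All three are computed in exact rational arithmetic, so the identity
``accuracy + error_rate == 100`` holds exactly, before any float formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .types import DegenerateInputError, FormatError

__all__ = [
    "ConfusionCounts",
    "confusion",
    "tp_rate",
    "accuracy",
    "error_rate",
    "position_errors",
]


@dataclass
class ConfusionCounts:
    """Pixel counts within the evaluation ROI."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tp_rate_fraction(self) -> Fraction:
        if self.tp + self.fp == 0:
            raise DegenerateInputError("no pixels identified as vein; TP rate undefined")
        return Fraction(100 * self.tp, self.tp + self.fp)

    @property
    def accuracy_fraction(self) -> Fraction:
        if self.total == 0:
            raise DegenerateInputError("empty ROI; accuracy undefined")
        return Fraction(100 * (self.tp + self.tn), self.total)

    @property
    def error_rate_fraction(self) -> Fraction:
        if self.total == 0:
            raise DegenerateInputError("empty ROI; error rate undefined")
        return Fraction(100 * (self.fp + self.fn), self.total)


def confusion(
    pred: np.ndarray, truth: np.ndarray, roi: np.ndarray
) -> ConfusionCounts:
    """Confusion counts of a binary detection against ground truth.

    Only pixels inside ``roi`` are counted; truth outside the ROI is ignored
    (mirroring the evaluation protocol where the manual labels are masked by
    the same ROI the detector saw).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not (pred.shape == truth.shape == roi.shape):
        raise FormatError("pred, truth and roi must share one shape")
    p = pred[roi]
    t = truth[roi]
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def tp_rate(c: ConfusionCounts) -> float:
    """True-positive vein detection rate, percent: 100*tp/(tp+fp)."""
    return float(c.tp_rate_fraction)


def accuracy(c: ConfusionCounts) -> float:
    """Overall correctness, percent: 100*(tp+tn)/total."""
    return float(c.accuracy_fraction)


def error_rate(c: ConfusionCounts) -> float:
    """Total error rate, percent: 100*(fp+fn)/total."""
    return float(c.error_rate_fraction)


def position_errors(
    estimated: np.ndarray, truth: np.ndarray
) -> dict[str, dict[str, float]]:
    """Per-axis absolute position-error statistics, in millimetres.

    ``estimated`` and ``truth`` are matched ``(N, 3)`` point lists in the TOF
    camera frame (x transverse, y longitudinal, z along the optical axis).
    Returns ``{"x": {"min", "max", "mean"}, "y": ..., "z": ...}``.
    """
    est = np.asarray(estimated, dtype=float).reshape(-1, 3)
    tru = np.asarray(truth, dtype=float).reshape(-1, 3)
    if est.shape != tru.shape:
        raise FormatError("estimated and truth point lists must have equal length")
    if est.shape[0] == 0:
        raise DegenerateInputError("no matched points")
    abs_err = np.abs(est - tru)
    return {
        axis: {
            "min": float(abs_err[:, i].min()),
            "max": float(abs_err[:, i].max()),
            "mean": float(abs_err[:, i].mean()),
        }
        for i, axis in enumerate(("x", "y", "z"))
    }
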