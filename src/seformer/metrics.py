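"""Hard segmentation metrics: Accuracy, Precision, mIoU, DSC (percent).

Vessel pixels are the positive class.  Dataset-level metrics are
micro-averaged: confusion counts are summed over all images first and the
metric formulas applied once to the summed table.

Degenerate 0/0 ratios (e.g. precision with no predicted positives) report
100 when the reference set is empty and the prediction agrees, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "confusion_counts", "segmentation_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    miou: float
    dsc: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "miou": self.miou, "dsc": self.dsc,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }

    def __str__(self):
        return (f"Accuracy {self.accuracy:.2f}%  Precision {self.precision:.2f}%  "
                f"mIoU {self.miou:.2f}%  DSC {self.dsc:.2f}%")


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        a = a.astype(bool)
    return a


def confusion_counts(pred, target) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, FN, TN) with vessel = positive class."""
    p = _as_binary(pred, "pred")
    t = _as_binary(target, "target")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float:
    # 0/0 -> perfect agreement on an empty reference set
    return 1.0 if den == 0 else num / den


def segmentation_metrics(counts) -> MetricsReport:
    """MetricsReport (percent) from a (TP, FP, FN, TN) confusion table."""
    tp, fp, fn, tn = (int(c) for c in counts)
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    n = tp + fp + fn + tn
    accuracy = _ratio(tp + tn, n)
    precision = _ratio(tp, tp + fp)
    iou_fg = _ratio(tp, tp + fp + fn)
    iou_bg = _ratio(tn, tn + fp + fn)
    dsc = _ratio(2 * tp, 2 * tp + fp + fn)
    return MetricsReport(
        accuracy=100.0 * accuracy,
        precision=100.0 * precision,
        miou=100.0 * (iou_fg + iou_bg) / 2.0,
        dsc=100.0 * dsc,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )
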