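"""Pixel-level segmentation evaluation.

Confusion matrix counts[true][pred] plus the derived per-class and macro
scores: pixel accuracy (PA = TP / (TP + FN), i.e. per-class recall), IoU,
precision, recall, and the F1 computed from the macro precision/recall.

Macro means include the background class; classes absent from both truth
and prediction have undefined ratios and are skipped from the macro mean
(the number of skipped classes is reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints, rows = truth, cols = prediction

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(np.int64)

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def tn(self) -> np.ndarray:
        return self.total - self.tp() - self.fn() - self.fp()

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion_matrix(pred, truth, num_classes: int) -> ConfusionMatrix:
    """Count pixels by (true class, predicted class)."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same shape")
    if pred.size == 0:
        raise ValueError("empty masks")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} contains class values outside 0..{num_classes - 1}")
    counts = np.bincount(
        truth.astype(np.int64) * num_classes + pred.astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro scores as fractions in [0, 1] (NaN = undefined)."""

    pixel_accuracy: np.ndarray
    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    mean_pixel_accuracy: float
    mean_iou: float
    macro_precision: float
    macro_recall: float
    f1: float
    skipped_classes: int = 0
    foreground_macro: bool = field(default=False)

    def as_dict(self) -> dict:
        pct = lambda x: round(100.0 * x, 2) if np.isfinite(x) else None
        return {
            "per_class": {
                "pixel_accuracy": [pct(v) for v in self.pixel_accuracy],
                "iou": [pct(v) for v in self.iou],
                "precision": [pct(v) for v in self.precision],
                "recall": [pct(v) for v in self.recall],
            },
            "mPA": pct(self.mean_pixel_accuracy),
            "mIoU": pct(self.mean_iou),
            "precision": pct(self.macro_precision),
            "recall": pct(self.macro_recall),
            "F1": pct(self.f1),
            "skipped_classes": self.skipped_classes,
            "foreground_macro": self.foreground_macro,
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def compute_metrics(cm: ConfusionMatrix, foreground_only: bool = False) -> MetricsReport:
    """Derive PA / IoU / precision / recall / F1 from a confusion matrix.

    ``foreground_only=True`` restricts the macro means to classes 1..C-1
    (the default includes background, which is what makes the published
    3-class mIoU/stem/leaf triples mutually consistent).
    """
    if cm.total <= 0:
        raise ValueError("confusion matrix is empty")
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    pa = _safe_div(tp, tp + fn)
    iou = _safe_div(tp, tp + fp + fn)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)

    sel = np.arange(cm.num_classes) >= (1 if foreground_only else 0)
    present = (tp + fp + fn) > 0  # class appears in truth or prediction
    keep = sel & present
    skipped = int(sel.sum() - keep.sum())

    def macro(values: np.ndarray) -> float:
        vals = values[keep]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    macro_p, macro_r = macro(precision), macro(recall)
    f1 = (
        2.0 * macro_p * macro_r / (macro_p + macro_r)
        if np.isfinite(macro_p) and np.isfinite(macro_r) and (macro_p + macro_r) > 0
        else float("nan")
    )
    return MetricsReport(
        pixel_accuracy=pa,
        iou=iou,
        precision=precision,
        recall=recall,
        mean_pixel_accuracy=macro(pa),
        mean_iou=macro(iou),
        macro_precision=macro_p,
        macro_recall=macro_r,
        f1=f1,
        skipped_classes=skipped,
        foreground_macro=foreground_only,
    )
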