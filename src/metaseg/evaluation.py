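"""Segmentation metrics: confusion counts, precision/recall/F1, IoU/mIoU,
and cohort summaries with t-based 95% confidence intervals.

Conventions: pixels labeled ignore (255) are excluded from every count.
For a class absent from both prediction and truth all its metrics are
1.0 (there was nothing to get wrong); when the denominator vanishes
otherwise the metric is 0.0. Per-slide mIoU is the mean of the
background and tumor IoUs; the cohort report gives mean, sample standard
deviation, standard error and the Student-t 95% CI for each metric, in
the usual results-table layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tile_grid import LABEL_IGNORE

METRIC_ORDER = ["precision", "recall", "f1", "iou_tumor", "iou_background", "miou"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     positive_class: int = 1) -> ConfusionCounts:
    """Exact pixel confusion counts; ignore-labeled truth pixels excluded."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    valid = truth != LABEL_IGNORE
    p = pred == positive_class
    t = truth == positive_class
    tp = int((p & t & valid).sum())
    fp = int((p & ~t & valid).sum())
    fn = int((~p & t & valid).sum())
    tn = int((~p & ~t & valid).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f1_iou(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2TP/(2TP+FP+FN); IoU = TP/(TP+FN+FP)."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0, 1.0  # class absent everywhere: nothing missed
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    iou = c.tp / (c.tp + c.fn + c.fp)
    return precision, recall, f1, iou


def miou(ious) -> float:
    """Arithmetic mean of per-class IoUs."""
    ious = list(ious)
    if not ious:
        raise ValueError("mIoU of an empty class list is undefined")
    return float(np.mean(ious))


def slide_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Tumor-class precision/recall/F1 plus per-class IoUs and mIoU."""
    c_tumor = confusion_counts(pred, truth, positive_class=1)
    c_bg = confusion_counts(pred, truth, positive_class=0)
    precision, recall, f1, iou_t = precision_recall_f1_iou(c_tumor)
    _, _, _, iou_b = precision_recall_f1_iou(c_bg)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "iou_tumor": iou_t,
        "iou_background": iou_b,
        "miou": miou([iou_b, iou_t]),
    }


@dataclass
class MetricsReport:
    per_slide: pd.DataFrame
    cohort: pd.DataFrame

    def to_csv(self, path) -> None:
        self.cohort.to_csv(path, index=False)


def cohort_report(per_slide_metrics: list[dict],
                  confidence: float = 0.95) -> MetricsReport:
    """Cohort summary: mean, sample SD, SE and Student-t CI per metric.

    With fewer than 2 slides the CI (and SD/SE) cannot be formed and is
    reported as NaN with a warning.
    """
    if not per_slide_metrics:
        raise ValueError("no slides to summarize")
    per_slide = pd.DataFrame(per_slide_metrics)
    n = len(per_slide)
    rows = []
    if n < 2:
        warnings.warn("fewer than 2 slides: confidence interval omitted",
                      RuntimeWarning)
    for metric in METRIC_ORDER:
        if metric not in per_slide:
            continue
        vals = per_slide[metric].to_numpy(dtype=float)
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            se = sd / np.sqrt(n)
            tcrit = float(stats.t.ppf(0.5 + confidence / 2, df=n - 1))
            lo, hi = mean - tcrit * se, mean + tcrit * se
        else:
            sd = se = lo = hi = float("nan")
        rows.append({
            "metric": metric,
            "mean": mean,
            "std_deviation": sd,
            "std_error": se,
            "ci95_lower": lo,
            "ci95_upper": hi,
        })
    return MetricsReport(per_slide=per_slide, cohort=pd.DataFrame(rows))
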