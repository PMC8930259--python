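"""Segmentation evaluation: precision rate and volume-fraction metrics.

Each class is scored one-vs-rest against a ground-truth label image:

* ``TPVF = TP / (TP + FN)`` — true-positive volume fraction, the share of the
  truth volume recovered (sensitivity);
* ``FNVF = FN / (TP + FN)`` — false-negative volume fraction, its complement;
* ``FPVF = FP / (FP + TN)`` — false-positive volume fraction, spill-over
  normalized by the truth-complement volume;
* ``PR = TP / (TP + FP)`` — precision rate, the positive predictive value.

A metric with an empty denominator is reported as missing (NaN), never as a
silent zero; macro averages are taken over the classes where the metric is
defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "tpvf",
    "fnvf",
    "fpvf",
    "precision_rate",
    "match_labels_by_overlap",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray, cls: int) -> ConfusionCounts:
    """One-vs-rest confusion counts of class ``cls``; TP counts the pixels
    labeled ``cls`` in both images."""
    pred, truth = _check_pair(pred, truth)
    p = pred == cls
    t = truth == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}"
        )
    return pred, truth


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def tpvf(c: ConfusionCounts) -> float:
    """True-positive volume fraction TP/(TP+FN); NaN if the truth class is empty."""
    return _ratio(c.tp, c.tp + c.fn)


def fnvf(c: ConfusionCounts) -> float:
    """False-negative volume fraction FN/(TP+FN); NaN if the truth class is empty."""
    return _ratio(c.fn, c.tp + c.fn)


def fpvf(c: ConfusionCounts) -> float:
    """False-positive volume fraction FP/(FP+TN); NaN if the truth class covers
    the whole image."""
    return _ratio(c.fp, c.fp + c.tn)


def precision_rate(c: ConfusionCounts) -> float:
    """Precision rate TP/(TP+FP); NaN when the class is never predicted."""
    return _ratio(c.tp, c.tp + c.fp)


def match_labels_by_overlap(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Greedily remap predicted labels onto truth classes by maximum overlap.

    Overlap pairs (pred label, truth class) are taken in decreasing pixel-count
    order; each pred label and each truth class is used at most once. Unmatched
    pred labels keep values outside the truth class set so they count as
    errors. Returns the remapped prediction.
    """
    pred, truth = _check_pair(pred, truth)
    pred_labels = np.unique(pred)
    truth_labels = np.unique(truth)
    overlaps = []
    for pl in pred_labels:
        sel = pred == pl
        for tl in truth_labels:
            n = int(np.count_nonzero(sel & (truth == tl)))
            if n > 0:
                overlaps.append((n, int(pl), int(tl)))
    # decreasing overlap; ties broken by (pred, truth) label for determinism
    overlaps.sort(key=lambda x: (-x[0], x[1], x[2]))
    mapping: dict[int, int] = {}
    used_truth: set[int] = set()
    for _, pl, tl in overlaps:
        if pl in mapping or tl in used_truth:
            continue
        mapping[pl] = tl
        used_truth.add(tl)
    spare = int(max(truth_labels.max(), pred_labels.max())) + 1
    out = np.empty_like(pred)
    for pl in pred_labels:
        if int(pl) in mapping:
            out[pred == pl] = mapping[int(pl)]
        else:
            out[pred == pl] = spare
            spare += 1
    return out


@dataclass(frozen=True)
class MetricReport:
    """Per-class metrics plus macro averages.

    ``per_class`` has one row per truth class with columns
    class, TP, FP, FN, TN, PR, TPVF, FNVF, FPVF; ``macro`` averages each
    metric over the classes where it is defined.
    """

    per_class: pd.DataFrame
    macro: dict[str, float]

    def to_csv(self, path) -> None:
        self.per_class.to_csv(path, index=False)


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    *,
    match: bool = False,
) -> MetricReport:
    """Score a predicted label image against ground truth, class by class.

    Classes are the distinct truth labels. By default predicted labels are
    compared as-is (the clusterer's ascending-center relabeling makes them
    comparable to phantom truth); ``match=True`` first applies the greedy
    maximum-overlap assignment of :func:`match_labels_by_overlap` — needed
    e.g. when a binary thresholder is scored against a many-class truth.
    """
    pred, truth = _check_pair(pred, truth)
    if match:
        pred = match_labels_by_overlap(pred, truth)
    rows = []
    for cls in np.unique(truth):
        c = confusion(pred, truth, int(cls))
        rows.append(
            {
                "class": int(cls),
                "TP": c.tp,
                "FP": c.fp,
                "FN": c.fn,
                "TN": c.tn,
                "PR": precision_rate(c),
                "TPVF": tpvf(c),
                "FNVF": fnvf(c),
                "FPVF": fpvf(c),
            }
        )
    per_class = pd.DataFrame(rows)
    macro = {
        m: float(per_class[m].mean(skipna=True)) for m in ("PR", "TPVF", "FNVF", "FPVF")
    }
    return MetricReport(per_class=per_class, macro=macro)
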