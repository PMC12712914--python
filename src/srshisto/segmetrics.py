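"""Per-class segmentation evaluation: confusion counts, overlap metrics,
boundary-F1 with a pixel tolerance, and match/mismatch error maps.

Conventions (segmentation-benchmark practice): a class absent from both truth
and prediction is excluded from the class means; a class absent from truth but
predicted contributes IoU = 0. Boundaries use 8-connectivity and Euclidean
distances; the default tolerance is 6 px, absorbing minor sectioning- and
registration-related boundary shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classes import N_CLASSES


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts per class: tp/fp/fn/tn arrays of length C."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def _check_pair(pred, truth, C):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    if C is not None and (pred.max(initial=0) >= C or truth.max(initial=0) >= C):
        raise ValueError("labels must be < C")
    return pred, truth


def confusion(pred: np.ndarray, truth: np.ndarray, C: int = N_CLASSES) -> ConfusionCounts:
    """Per-class one-vs-rest confusion counts from two label maps."""
    pred, truth = _check_pair(pred, truth, C)
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (truth.ravel(), pred.ravel()), 1)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


@dataclass
class MetricReport:
    """Per-class metrics in [0, 1] with unweighted class means.

    ``present`` marks classes that exist in truth or prediction; absent
    classes are excluded from the means. ``bf1`` may be NaN when not computed.
    """

    iou: np.ndarray
    acc: np.ndarray
    dice: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    present: np.ndarray
    bf1: np.ndarray | None = None

    def _mean(self, arr):
        return float(arr[self.present].mean()) if self.present.any() else float("nan")

    @property
    def miou(self): return self._mean(self.iou)

    @property
    def macc(self): return self._mean(self.acc)

    @property
    def mdice(self): return self._mean(self.dice)

    @property
    def mprecision(self): return self._mean(self.precision)

    @property
    def mrecall(self): return self._mean(self.recall)

    @property
    def mbf1(self):
        return self._mean(self.bf1) if self.bf1 is not None else float("nan")

    def as_percent_table(self) -> dict:
        """Report formatted as percentages with 2 decimals per class."""
        out = {}
        for k in np.flatnonzero(self.present):
            row = {"IoU": round(100 * self.iou[k], 2),
                   "Acc": round(100 * self.acc[k], 2),
                   "Dice": round(100 * self.dice[k], 2),
                   "Precision": round(100 * self.precision[k], 2),
                   "Recall": round(100 * self.recall[k], 2)}
            if self.bf1 is not None:
                row["BF1"] = round(100 * self.bf1[k], 2)
            out[int(k)] = row
        means = {"mIoU": round(100 * self.miou, 2), "mAcc": round(100 * self.macc, 2),
                 "mDice": round(100 * self.mdice, 2),
                 "mPrecision": round(100 * self.mprecision, 2),
                 "mRecall": round(100 * self.mrecall, 2)}
        if self.bf1 is not None:
            means["mBF1"] = round(100 * self.mbf1, 2)
        out["means"] = means
        return out


def class_metrics(counts: ConfusionCounts) -> MetricReport:
    """IoU, accuracy, Dice, precision and recall from confusion counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    iou = _safe_div(tp, tp + fp + fn)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    acc = _safe_div(tp + tn, tp + fp + fn + tn)
    dice = _safe_div(2 * tp, 2 * tp + fp + fn)
    present = (tp + fp + fn) > 0
    return MetricReport(iou=iou, acc=acc, dice=dice, precision=precision,
                        recall=recall, present=present)


def boundary_pixels(labels: np.ndarray, k: int) -> np.ndarray:
    """Pixels of class k with at least one differing 8-neighbour.

    The raster edge is padded by replication, so pixels on the image border
    are boundary only if an in-image neighbour differs.
    """
    mask = labels == k
    padded = np.pad(mask, 1, mode="edge")
    neigh_all = np.ones_like(mask)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            neigh_all &= padded[1 + dy:1 + dy + mask.shape[0],
                                1 + dx:1 + dx + mask.shape[1]]
    return mask & ~neigh_all


def boundary_f1(pred: np.ndarray, truth: np.ndarray, tolerance: float = 6.0,
                C: int = N_CLASSES) -> np.ndarray:
    """Symmetric boundary-F1 per class at a Euclidean pixel tolerance.

    Precision counts predicted boundary pixels within ``tolerance`` of a truth
    boundary pixel; recall symmetrically. Classes absent from both maps get
    NaN; a class present in one map only gets 0.
    """
    pred, truth = _check_pair(pred, truth, C)
    out = np.full(C, np.nan)
    for k in range(C):
        in_pred = bool((pred == k).any())
        in_truth = bool((truth == k).any())
        if not in_pred and not in_truth:
            continue
        bp = boundary_pixels(pred, k)
        bt = boundary_pixels(truth, k)
        if not bp.any() and not bt.any():
            # class fills each map it appears in: identical coverage counts as 1
            out[k] = 1.0 if (in_pred == in_truth) else 0.0
            continue
        if not bp.any() or not bt.any():
            out[k] = 0.0
            continue
        dist_to_truth = ndimage.distance_transform_edt(~bt)
        dist_to_pred = ndimage.distance_transform_edt(~bp)
        prec = float((dist_to_truth[bp] <= tolerance).mean())
        rec = float((dist_to_pred[bt] <= tolerance).mean())
        out[k] = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return out


def evaluate(pred: np.ndarray, truth: np.ndarray, tolerance: float = 6.0,
             C: int = N_CLASSES) -> MetricReport:
    """Full per-class report including boundary-F1."""
    report = class_metrics(confusion(pred, truth, C))
    report.bf1 = np.nan_to_num(boundary_f1(pred, truth, tolerance, C), nan=0.0)
    return report


ERROR_MATCH, ERROR_MISMATCH, ERROR_IGNORED = 0, 1, 2


def error_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Ternary raster: 0 match, 1 mismatch, 2 ignored (background in both)."""
    pred, truth = _check_pair(pred, truth, None)
    out = np.where(pred == truth, ERROR_MATCH, ERROR_MISMATCH).astype(np.uint8)
    out[(pred == 0) & (truth == 0)] = ERROR_IGNORED
    return out
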