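"""Segmentation evaluation suite: Dice, IOU, ACC, G-mean, Cohen's kappa, AUC.

Metrics are computed per image from pixel-level confusion counts (foreground
is the positive class) and then aggregated as mean +/- population standard
deviation over test images, overall and per thrombus subgroup — the
reporting convention of the study this package reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = ("dice", "iou", "acc", "gmean", "kappa", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts for one image."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    u = np.unique(a)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {u[:10]}")
    return a.astype(np.int64)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    p = _check_binary(pred, "pred")
    g = _check_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.sum((p == 1) & (g == 1)))
    fp = int(np.sum((p == 1) & (g == 0)))
    tn = int(np.sum((p == 0) & (g == 0)))
    fn = int(np.sum((p == 0) & (g == 1)))
    return ConfusionCounts(tp, fp, tn, fn)


def dice(c: ConfusionCounts) -> float:
    denom = c.fp + c.fn + 2 * c.tp
    if denom == 0:           # empty gt and empty pred: perfect agreement
        return 1.0
    return 2.0 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.fp + c.fn + c.tp
    if denom == 0:
        return 1.0
    return c.tp / denom


def acc(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def gmean(c: ConfusionCounts) -> float:
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 1.0
    return float(np.sqrt(sens * spec))


def kappa(c: ConfusionCounts) -> float:
    """Chance-corrected agreement with the chance term computed from the
    marginals: p_e = ((TP+FN)(TP+FP) + (TN+FP)(TN+FN)) / N^2."""
    n = c.total
    pe = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / (n * n)
    a = acc(c)
    if abs(1.0 - pe) < 1e-15:
        # both rater marginals are single-class; agreement is either perfect
        # or impossible to chance-correct
        return 1.0 if (c.fp + c.fn) == 0 else 0.0
    return (a - pe) / (1.0 - pe)


def auc(prob: np.ndarray, gt: np.ndarray) -> float:
    """Area under the ROC curve over all pixel-score thresholds.

    Computed as the Mann-Whitney statistic with midrank tie handling, which
    equals the trapezoidal area over the distinct score values.  Returns NaN
    (with a warning) when the ground truth contains a single class.
    """
    p = np.asarray(prob, dtype=float).ravel()
    g = _check_binary(gt, "gt").ravel()
    if p.shape != g.shape:
        raise ValueError("prob and gt must have the same number of pixels")
    n_pos = int(g.sum())
    n_neg = g.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class ground truth; recording NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[g == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def image_metrics(prob: np.ndarray, pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """All six metrics for one image (prob map, thresholded pred, gt mask)."""
    c = confusion_counts(pred, gt)
    return {
        "dice": dice(c), "iou": iou(c), "acc": acc(c),
        "gmean": gmean(c), "kappa": kappa(c), "auc": auc(prob, gt),
    }


@dataclass
class MetricReport:
    """Per-image metric rows plus mean +/- std aggregates."""

    per_image: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        per = self.per_image.copy()
        per.insert(0, "row_type", "image")
        summ = self.summary.copy()
        summ.insert(0, "row_type", "summary")
        pd.concat([per, summ], ignore_index=True).to_csv(path, index=False)


def _aggregate(df: pd.DataFrame, group: str) -> dict:
    row: dict = {"group": group, "n": len(df)}
    for m in METRIC_NAMES:
        vals = df[m].dropna().to_numpy(dtype=float)
        row[f"{m}_mean"] = float(vals.mean()) if vals.size else float("nan")
        row[f"{m}_std"] = float(vals.std()) if vals.size else float("nan")  # population std
    return row


def evaluate(predictions, records, out_csv: str | Path | None = None) -> MetricReport:
    """Score a list of predictions against their ground truths.

    Parameters
    ----------
    predictions
        List of ``(prob_map, pred_mask)`` pairs aligned index-for-index with
        ``records``.
    records
        List of objects with ``sample_id``, ``thrombus`` and a ground-truth
        mask attached as ``(record, gt_mask)`` tuples, or plain
        ``(sample_id, thrombus, gt_mask)`` tuples.
    """
    rows = []
    for i, rec in enumerate(records):
        if i >= len(predictions) or predictions[i] is None:
            raise ValueError(f"missing prediction for sample index {i}: {rec!r}")
        prob, pred = predictions[i]
        if hasattr(rec, "sample_id"):
            sid, thr, gt = rec.sample_id, rec.thrombus, rec.gt_mask
        else:
            sid, thr, gt = rec
        m = image_metrics(prob, pred, gt)
        rows.append({"sample_id": sid, "thrombus": bool(thr), **m})
    per_image = pd.DataFrame(rows)
    groups = [_aggregate(per_image, "overall")]
    for flag, name in ((False, "non_thrombus"), (True, "thrombus")):
        sub = per_image[per_image["thrombus"] == flag]
        if len(sub):
            groups.append(_aggregate(sub, name))
    summary = pd.DataFrame(groups)
    report = MetricReport(per_image=per_image, summary=summary)
    if out_csv is not None:
        report.to_csv(out_csv)
    return report
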