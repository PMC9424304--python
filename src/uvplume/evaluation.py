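"""Segmentation evaluation: per-class confusion counts, IOU, precision,
recall, and batch summaries.

All single-class metrics are reported for the plumage class; mean IOU
averages the plumage and non-plumage classes.  Undefined ratios (zero
denominator) raise :class:`~uvplume.errors.UndefinedMetric` and are
propagated as missing values in batch summaries rather than reported
as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeError, UndefinedMetric

logger = logging.getLogger(__name__)

THRESHOLDS = (0.90, 0.75, 0.50)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies for one class: TP, FN, FP, TN."""

    p_ii: int  # class pixels predicted as the class (true positive)
    p_ij: int  # class pixels predicted as other (false negative)
    p_ji: int  # other pixels predicted as the class (false positive)
    p_jj: int  # other pixels predicted as other (true negative)

    @property
    def total(self) -> int:
        return self.p_ii + self.p_ij + self.p_ji + self.p_jj


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies for the plumage (True) class."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        p_ii=int(np.sum(truth & pred)),
        p_ij=int(np.sum(truth & ~pred)),
        p_ji=int(np.sum(~truth & pred)),
        p_jj=int(np.sum(~truth & ~pred)),
    )


def iou(counts: ConfusionCounts) -> float:
    denom = counts.p_ii + counts.p_ij + counts.p_ji
    if denom == 0:
        raise UndefinedMetric("IOU undefined: empty prediction and truth")
    return counts.p_ii / denom


def precision(counts: ConfusionCounts) -> float:
    denom = counts.p_ii + counts.p_ji
    if denom == 0:
        raise UndefinedMetric("precision undefined: empty prediction")
    return counts.p_ii / denom


def recall(counts: ConfusionCounts) -> float:
    denom = counts.p_ii + counts.p_ij
    if denom == 0:
        raise UndefinedMetric("recall undefined: empty truth")
    return counts.p_ii / denom


def _swap_class(counts: ConfusionCounts) -> ConfusionCounts:
    return ConfusionCounts(counts.p_jj, counts.p_ji, counts.p_ij, counts.p_ii)


def mean_iou(counts: ConfusionCounts) -> float:
    """Unweighted mean of the plumage and non-plumage class IOUs."""
    return float(np.mean([iou(counts), iou(_swap_class(counts))]))


def _safe(metric, counts):
    try:
        return metric(counts)
    except UndefinedMetric:
        return np.nan


def evaluate_pair(pred: np.ndarray, truth: np.ndarray) -> dict:
    counts = confusion(pred, truth)
    return {
        "iou": _safe(iou, counts),
        "precision": _safe(precision, counts),
        "recall": _safe(recall, counts),
        "mean_iou": _safe(mean_iou, counts),
    }


def evaluate_batch(pairs, groups=None, thresholds=THRESHOLDS):
    """Evaluate (pred, truth) mask pairs; return (per-image, summary) tables.

    ``groups`` optionally labels each pair (e.g. by view); the summary
    then also carries per-group means.  Fractions above each threshold
    use a strict comparison and exclude undefined (NaN) records.
    """
    records = []
    for i, (pred, truth) in enumerate(pairs):
        rec = evaluate_pair(pred, truth)
        rec["image"] = i
        rec["group"] = groups[i] if groups is not None else "all"
        records.append(rec)
    if not records:
        raise ValueError("no mask pairs to evaluate")
    per_image = pd.DataFrame.from_records(records).set_index("image")

    n_undef = int(per_image[["iou", "precision", "recall"]].isna().any(axis=1).sum())
    if n_undef:
        logger.warning("%d image(s) had undefined metrics (excluded from means)", n_undef)

    rows = []
    metric_cols = ["iou", "precision", "recall", "mean_iou"]
    scopes = [("overall", per_image)]
    if groups is not None:
        scopes += [(g, df) for g, df in per_image.groupby("group", sort=True)]
    for name, df in scopes:
        row = {"group": name, "n": len(df)}
        for m in metric_cols:
            row[f"mean_{m}"] = df[m].mean()
            row[f"min_{m}"] = df[m].min()
        for t in thresholds:
            row[f"frac_iou_gt_{t:.2f}"] = (df["iou"] > t).sum() / df["iou"].notna().sum()
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group")
    return per_image, summary
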