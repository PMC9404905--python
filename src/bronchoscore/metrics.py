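"""Evaluation statistics: box IOU, confusion bookkeeping, sensitivity/specificity.

The evaluation unit is per-lobe-per-image: each lobe of each evaluated slice
is one unit, positive in truth if it contains at least one annotated lesion
and positive in prediction if at least one detection was assigned to it.
Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP) over these units.
Localized agreement (IOU of matched prediction/truth pairs, class accuracy
over matched pairs) is reported separately from the unit-level counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvaluationUnit",
    "box_iou",
    "confusion_from_detections",
    "sensitivity",
    "specificity",
    "classification_accuracy",
    "match_boxes",
    "mean_matched_iou",
]

Box = tuple[float, float, float, float]  # x, y, w, h


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class EvaluationUnit:
    """One per-lobe evaluation unit: its truth boxes and its detections.

    ``pred_boxes`` entries may carry a confidence (box, confidence) or be
    bare boxes; ``pred_classes``/``truth_classes`` are optional parallel
    severity labels used for matched-pair class accuracy.
    """

    truth_boxes: list[Box] = field(default_factory=list)
    pred_boxes: list[Box] = field(default_factory=list)
    pred_confidences: list[float] | None = None
    truth_classes: list[int] | None = None
    pred_classes: list[int] | None = None


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two [x, y, w, h] boxes; 0 for empty union."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw < 0 or ah < 0 or bw < 0 or bh < 0:
        raise ValueError("box extents must be non-negative")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    if union <= 0:
        return 0.0
    return min(inter / union, 1.0)  # guard roundoff for near-identical boxes


def match_boxes(
    pred_boxes: list[Box],
    truth_boxes: list[Box],
    confidences: list[float] | None = None,
    iou_threshold: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching by descending confidence.

    Returns (pred_index, truth_index, iou) triples for pairs with
    IOU >= ``iou_threshold``.
    """
    order = range(len(pred_boxes))
    if confidences is not None:
        order = sorted(order, key=lambda i: -confidences[i])
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        best_iou, best_t = 0.0, -1
        for ti, tb in enumerate(truth_boxes):
            if ti in matched_truth:
                continue
            iou = box_iou(pred_boxes[pi], tb)
            if iou > best_iou:
                best_iou, best_t = iou, ti
        if best_t >= 0 and best_iou >= iou_threshold:
            matched_truth.add(best_t)
            pairs.append((pi, best_t, best_iou))
    return pairs


def confusion_from_detections(
    units: list[EvaluationUnit], iou_threshold: float = 0.5
) -> tuple[ConfusionCounts, dict]:
    """Tally per-unit TP/FP/TN/FN and matched-pair localization stats.

    A unit is truth-positive if it holds >= 1 annotation and
    prediction-positive if it holds >= 1 detection (a mislocated detection
    still marks its unit predicted-positive). Returns the counts and a stats
    dict with mean matched IOU and matched (pred, truth) class pairs.
    """
    if not units:
        raise ValueError("at least one evaluation unit is required")
    counts = ConfusionCounts()
    matched_ious: list[float] = []
    class_pairs: list[tuple[int, int]] = []
    for u in units:
        t_pos = len(u.truth_boxes) > 0
        p_pos = len(u.pred_boxes) > 0
        if t_pos and p_pos:
            counts = counts + ConfusionCounts(tp=1)
        elif t_pos:
            counts = counts + ConfusionCounts(fn=1)
        elif p_pos:
            counts = counts + ConfusionCounts(fp=1)
        else:
            counts = counts + ConfusionCounts(tn=1)
        for pi, ti, iou in match_boxes(
            u.pred_boxes, u.truth_boxes, u.pred_confidences, iou_threshold
        ):
            matched_ious.append(iou)
            if u.pred_classes is not None and u.truth_classes is not None:
                class_pairs.append((u.pred_classes[pi], u.truth_classes[ti]))
    stats = {
        "mean_matched_iou": float(np.mean(matched_ious)) if matched_ious else None,
        "n_matched": len(matched_ious),
        "class_pairs": class_pairs,
    }
    return counts, stats


def mean_matched_iou(units: list[EvaluationUnit], iou_threshold: float = 0.5) -> float | None:
    """Mean IOU over matched prediction/truth pairs (None when no matches)."""
    _, stats = confusion_from_detections(units, iou_threshold)
    return stats["mean_matched_iou"]


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); raises when there are no truth-positive units."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive-truth units (tp + fn == 0)")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); raises when there are no truth-negative units."""
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no negative-truth units (tn + fp == 0)")
    return c.tn / (c.tn + c.fp)


def classification_accuracy(
    pred_classes: list[int], truth_classes: list[int]
) -> tuple[float, dict[int, float]]:
    """Exact-agreement fraction over matched detections, plus per-class rates.

    Per-class accuracy for class c is the agreement rate over pairs whose
    predicted class is c (the fraction of class-c calls that are correct).
    """
    if len(pred_classes) != len(truth_classes):
        raise ValueError("pred and truth class lists must have equal length")
    if not truth_classes:
        raise ValueError("empty class lists")
    pred = np.asarray(pred_classes)
    truth = np.asarray(truth_classes)
    overall = float(np.mean(pred == truth))
    per_class: dict[int, float] = {}
    for c in sorted(set(pred_classes)):
        sel = pred == c
        per_class[int(c)] = float(np.mean(pred[sel] == truth[sel]))
    return overall, per_class
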