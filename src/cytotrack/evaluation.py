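"""Tracking/detection evaluation against annotated ground truth.

Two headline metrics suit datasets whose annotation is *incomplete* (only
a curated subset of objects is labeled, so extra predictions cannot be
scored as false positives):

* **Modified Recall** — ``100 * sum_frames TP / sum_frames (TP + FN)``:
  the fraction of annotated boxes recovered, pooled over frames.
  Unmatched predictions are simply ignored, so the metric is monotone
  non-decreasing as predictions are added.
* **Average IoU** — ``100 * mean(IoU_i)`` over the matched ground-truth /
  prediction pairs only: localization quality of what *was* recovered.

Ground truth and predictions are paired per frame by greedy one-to-one
matching on descending IoU, rejecting pairs below a threshold (default
0.5); ties break toward the lowest (gt, prediction) indices.

An identity-switch counter supports trajectory-continuity checks: it
counts the frames where an annotated object's matched predicted identity
differs from the identity it was matched to previously.  The count is
invariant to any fixed relabeling of predicted ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, iou_matrix

__all__ = [
    "FrameCounts",
    "MatchReport",
    "match_frame",
    "evaluate_sequences",
    "modified_recall",
    "average_iou",
    "count_id_switches",
    "UndefinedMetricError",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric requested with an empty denominator (no GT / no matches)."""


@dataclass
class FrameCounts:
    frame_index: int
    tp: int
    fn: int
    matched_ious: list[float]


@dataclass
class MatchReport:
    """Accumulated per-frame matching outcomes."""

    per_frame: list[FrameCounts] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return sum(f.tp for f in self.per_frame)

    @property
    def fn(self) -> int:
        return sum(f.fn for f in self.per_frame)

    @property
    def matched_pairs(self) -> int:
        return sum(len(f.matched_ious) for f in self.per_frame)

    @property
    def iou_sum(self) -> float:
        return sum(sum(f.matched_ious) for f in self.per_frame)

    def add(self, other: "FrameCounts") -> None:
        self.per_frame.append(other)


def match_frame(
    gt_boxes: Sequence[BoundingBox],
    pred_boxes: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[list[tuple[int, int, float]], int, int]:
    """Greedily pair GT and predicted boxes by descending IoU.

    Returns ``(pairs, TP, FN)`` where each pair is
    ``(gt_index, pred_index, iou)``.  Each box participates in at most one
    pair; pairs below the IoU threshold are rejected.  Unmatched
    predictions are not counted — the evaluation deliberately does not
    penalize false positives.
    """
    n_gt, n_pred = len(gt_boxes), len(pred_boxes)
    if n_gt == 0 or n_pred == 0:
        return [], 0, n_gt
    overlap = iou_matrix(list(gt_boxes), list(pred_boxes))
    gi, pj = np.nonzero(overlap >= iou_threshold)
    # Sort candidates by IoU descending, ties toward low (gt, pred) index.
    order = sorted(range(len(gi)), key=lambda k: (-overlap[gi[k], pj[k]], gi[k], pj[k]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        g, p = int(gi[k]), int(pj[k])
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        pairs.append((g, p, float(overlap[g, p])))
    tp = len(pairs)
    return sorted(pairs), tp, n_gt - tp


def evaluate_sequences(
    gt_stream: dict[int, list[tuple[int, BoundingBox]]],
    pred_stream: dict[int, list[tuple[int, BoundingBox]]],
    iou_threshold: float = 0.5,
) -> MatchReport:
    """Match every GT frame against predictions and accumulate counts.

    Streams map frame index to ``(object_id, box)`` lists; ids are ignored
    here (see :func:`count_id_switches` for identity accounting).  Frames
    with GT but no predictions contribute pure false negatives.
    """
    report = MatchReport()
    for frame_index in sorted(gt_stream):
        gt_boxes = [b for _, b in gt_stream[frame_index]]
        pred_boxes = [b for _, b in pred_stream.get(frame_index, [])]
        pairs, tp, fn = match_frame(gt_boxes, pred_boxes, iou_threshold)
        report.add(
            FrameCounts(
                frame_index=frame_index,
                tp=tp,
                fn=fn,
                matched_ious=[iou for _, _, iou in pairs],
            )
        )
    return report


def modified_recall(report: MatchReport) -> float:
    """Percent of annotated boxes recovered: ``100 * TP / (TP + FN)``."""
    denom = report.tp + report.fn
    if denom == 0:
        raise UndefinedMetricError("no ground-truth boxes: recall undefined")
    return 100.0 * report.tp / denom


def average_iou(report: MatchReport) -> float:
    """Mean IoU over matched pairs, as a percentage."""
    if report.matched_pairs == 0:
        raise UndefinedMetricError("no matched pairs: average IoU undefined")
    return 100.0 * report.iou_sum / report.matched_pairs


def count_id_switches(
    gt_stream: dict[int, list[tuple[int, BoundingBox]]],
    pred_stream: dict[int, list[tuple[int, BoundingBox]]],
    iou_threshold: float = 0.5,
) -> int:
    """Frames where a GT object's matched predicted identity changes.

    Each frame, GT boxes are matched to predicted boxes as in
    :func:`match_frame`; a switch is counted when a GT id that was
    previously matched to predicted id ``p`` is now matched to ``q != p``.
    The first match of a GT id never counts, so the result is invariant to
    any fixed bijective renaming of predicted ids.
    """
    last_match: dict[int, int] = {}
    switches = 0
    for frame_index in sorted(gt_stream):
        gt = gt_stream[frame_index]
        pred = pred_stream.get(frame_index, [])
        pairs, _, _ = match_frame(
            [b for _, b in gt], [b for _, b in pred], iou_threshold
        )
        for g, p, _ in pairs:
            gt_id = gt[g][0]
            pred_id = pred[p][0]
            if gt_id in last_match and last_match[gt_id] != pred_id:
                switches += 1
            last_match[gt_id] = pred_id
    return switches
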