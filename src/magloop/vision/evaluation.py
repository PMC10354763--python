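"""Detector evaluation: greedy matching, 101-point AP, COCO-style mAP sweep.

Matching follows the standard protocol: within each class and IoU threshold,
detections are ranked by descending confidence (ties broken by frame order,
then list index) and greedily matched to the unmatched ground-truth box of
highest IoU at/above the threshold (IoU ties broken by lower truth index).
Duplicate detections on one truth count as false positives.  AP uses 101-point
interpolated precision; ``map_coco`` averages AP over the full class x
threshold grid with thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from magloop.labels import CLASS_DROPLET, CLASS_PARTICLE
from magloop.vision.boxes import BoundingBox, iou
from magloop.vision.detector import Detection

IOU_SWEEP = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))
DEFAULT_CLASSES = (CLASS_DROPLET, CLASS_PARTICLE)

# ground truth for one frame: list of (class_label, BoundingBox)
Truth = tuple[str, BoundingBox]


@dataclass
class EvaluationReport:
    per_class_ap: dict[str, dict[float, float]]
    map_coco: float
    pr_points: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


class AlignmentError(ValueError):
    """Raised when detection and truth frame ids do not line up."""


def _ranked(detections: Mapping[str, Sequence[Detection]], class_label: str):
    """All detections of a class, ranked by descending confidence."""
    entries = []
    for frame_order, frame_id in enumerate(detections):
        for index, det in enumerate(detections[frame_id]):
            if det.class_label == class_label:
                entries.append((-det.confidence, frame_order, index, frame_id, det))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    return [(frame_id, det) for _, _, _, frame_id, det in entries]


def _match_class(ranked, truths_by_frame, threshold: float):
    """Greedy matching; returns (tp_flags, n_truth)."""
    matched: dict[str, set[int]] = {fid: set() for fid in truths_by_frame}
    n_truth = sum(len(t) for t in truths_by_frame.values())
    tp_flags: list[bool] = []
    for frame_id, det in ranked:
        best_iou, best_j = 0.0, -1
        for j, truth_box in enumerate(truths_by_frame[frame_id]):
            if j in matched[frame_id]:
                continue
            v = iou(det.box, truth_box)
            if v >= threshold and v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[frame_id].add(best_j)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    return tp_flags, n_truth


def average_precision(tp_flags: Sequence[bool], n_truth: int) -> float:
    """101-point interpolated AP from ranked true/false-positive flags."""
    if n_truth == 0:
        return 0.0
    tp = np.cumsum(np.asarray(tp_flags, dtype=float)) if tp_flags else np.array([])
    if tp.size == 0:
        return 0.0
    fp = np.arange(1, tp.size + 1) - tp
    recall = tp / n_truth
    precision = tp / (tp + fp)
    # precision envelope, then sample at 101 evenly spaced recall points
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += envelope[idx] if idx < envelope.size else 0.0
    return float(ap / 101.0)


def pr_curve(tp_flags: Sequence[bool], n_truth: int) -> list[tuple[float, float]]:
    if n_truth == 0 or not tp_flags:
        return []
    tp = np.cumsum(np.asarray(tp_flags, dtype=float))
    fp = np.arange(1, tp.size + 1) - tp
    recall = tp / n_truth
    precision = tp / (tp + fp)
    return list(zip(recall.tolist(), precision.tolist()))


def evaluate(
    detections: Mapping[str, Sequence[Detection]],
    truths: Mapping[str, Sequence[Truth]],
    iou_thresholds: Sequence[float] = IOU_SWEEP,
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> EvaluationReport:
    """Score per-frame detections against aligned per-frame ground truth."""
    if set(detections) != set(truths):
        raise AlignmentError("detection and truth frame ids differ")
    per_class_ap: dict[str, dict[float, float]] = {}
    pr_points: dict[str, list[tuple[float, float]]] = {}
    for class_label in classes:
        ranked = _ranked(detections, class_label)
        truth_boxes = {fid: [box for lbl, box in truths[fid] if lbl == class_label] for fid in truths}
        per_class_ap[class_label] = {}
        for threshold in iou_thresholds:
            tp_flags, n_truth = _match_class(ranked, truth_boxes, threshold)
            per_class_ap[class_label][threshold] = average_precision(tp_flags, n_truth)
        tp_flags, n_truth = _match_class(ranked, truth_boxes, 0.5)
        pr_points[class_label] = pr_curve(tp_flags, n_truth)
    all_aps = [ap for by_thr in per_class_ap.values() for ap in by_thr.values()]
    return EvaluationReport(
        per_class_ap=per_class_ap,
        map_coco=float(sum(all_aps) / len(all_aps)) if all_aps else 0.0,
        pr_points=pr_points,
    )


def split_dataset(frames: Sequence, train_fraction: float, seed: int) -> tuple[list, list]:
    """Deterministic shuffled split; train size = floor(n * train_fraction)."""
    if len(frames) == 0:
        raise ValueError("cannot split an empty collection")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    order = np.random.default_rng(seed).permutation(len(frames))
    n_train = math.floor(len(frames) * train_fraction)
    train = [frames[i] for i in order[:n_train]]
    test = [frames[i] for i in order[n_train:]]
    return train, test
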