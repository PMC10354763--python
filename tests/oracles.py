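"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths under test: box overlap goes through
shapely polygons, AP through plain-Python loops, and HSV through colorsys.
"""

from __future__ import annotations

import colorsys

from shapely.geometry import box as shapely_box


def iou_oracle(a, b) -> float:
    """IoU via shapely polygon intersection/union."""
    pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
    pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def ap_oracle(flags: list[bool], n_truth: int) -> float:
    """101-point interpolated AP from ranked TP/FP flags, plain loops."""
    if n_truth == 0 or not flags:
        return 0.0
    points = []
    tp = 0
    for k, flag in enumerate(flags, start=1):
        tp += int(flag)
        points.append((tp / n_truth, tp / k))
    total = 0.0
    for i in range(101):
        r = i / 100.0
        best = 0.0
        for recall, precision in points:
            if recall >= r and precision > best:
                best = precision
        total += best
    return total / 101.0


def evaluate_oracle(detections, truths, thresholds, classes) -> dict:
    """Brute-force per-class AP grid matching the documented protocol.

    Detections ranked by (-confidence, frame order, index); each greedily takes
    the unmatched truth of highest oracle-IoU at/above the threshold, lower
    truth index on ties.
    """
    per_class = {}
    for cls in classes:
        ranked = []
        for frame_order, fid in enumerate(detections):
            for index, det in enumerate(detections[fid]):
                if det.class_label == cls:
                    ranked.append((-det.confidence, frame_order, index, fid, det))
        ranked.sort(key=lambda e: (e[0], e[1], e[2]))
        truth_boxes = {fid: [b for lbl, b in truths[fid] if lbl == cls] for fid in truths}
        n_truth = sum(len(v) for v in truth_boxes.values())
        per_class[cls] = {}
        for thr in thresholds:
            used = {fid: set() for fid in truth_boxes}
            flags = []
            for _, _, _, fid, det in ranked:
                best_iou, best_j = 0.0, -1
                for j, tb in enumerate(truth_boxes[fid]):
                    if j in used[fid]:
                        continue
                    v = iou_oracle(det.box, tb)
                    if v >= thr and v > best_iou:
                        best_iou, best_j = v, j
                if best_j >= 0:
                    used[fid].add(best_j)
                    flags.append(True)
                else:
                    flags.append(False)
            per_class[cls][thr] = ap_oracle(flags, n_truth)
    return per_class


def hue_saturation_oracle(rgb) -> tuple[float, float]:
    """(hue degrees, saturation) via colorsys."""
    h, s, _ = colorsys.rgb_to_hsv(rgb[0] / 255.0, rgb[1] / 255.0, rgb[2] / 255.0)
    return h * 360.0, s
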