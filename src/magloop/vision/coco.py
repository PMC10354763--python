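"""COCO JSON annotation interchange and line-delimited detection records.

The annotation schema is the standard one: top-level ``images`` /
``annotations`` / ``categories`` arrays, ``bbox`` as ``[x, y, width, height]``
in pixels, category ids 1 = droplet and 2 = particle.  Detections interchange
as JSON-lines records ``{"frame_id", "class", "bbox", "confidence"}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio

from magloop.labels import CLASS_DROPLET, CLASS_PARTICLE
from magloop.vision.boxes import BoundingBox
from magloop.vision.detector import Detection

CATEGORY_IDS = {CLASS_DROPLET: 1, CLASS_PARTICLE: 2}
CATEGORY_NAMES = {v: k for k, v in CATEGORY_IDS.items()}


def write_coco(
    frames: Sequence[AnnotatedFrame],
    json_path: Union[str, Path],
    images_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Write annotations (and optionally PNG images) for a set of frames."""
    images, annotations = [], []
    ann_id = 1
    for image_id, frame in enumerate(frames, start=1):
        if frame.image is not None:
            height, width = frame.image.shape[:2]
        else:
            height = width = 0
        file_name = f"{frame.frame_id}.png"
        images.append({"id": image_id, "file_name": file_name, "width": width, "height": height})
        if images_dir is not None and frame.image is not None:
            iio.imwrite(Path(images_dir) / file_name, frame.image)
        for ann in frame.annotations:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_id,
                    "category_id": CATEGORY_IDS[ann.class_label],
                    "bbox": [round(v, 3) for v in ann.box.as_xywh()],
                    "area": round(ann.box.area, 3),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": cid, "name": name} for name, cid in CATEGORY_IDS.items()],
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh)
    return doc


def read_coco(json_path: Union[str, Path]) -> dict[str, list[tuple[str, BoundingBox]]]:
    """Read a COCO file into per-frame ground truth keyed by file-name stem."""
    with open(json_path) as fh:
        doc = json.load(fh)
    names = {c["id"]: c["name"] for c in doc.get("categories", [])} or CATEGORY_NAMES
    frames: dict[int, str] = {}
    truths: dict[str, list[tuple[str, BoundingBox]]] = {}
    for img in doc["images"]:
        key = Path(img["file_name"]).stem
        frames[img["id"]] = key
        truths[key] = []
    for ann in doc["annotations"]:
        box = BoundingBox.from_xywh(*ann["bbox"])
        truths[frames[ann["image_id"]]].append((names[ann["category_id"]], box))
    return truths


def write_detections(detections: dict[str, Sequence[Detection]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for frame_id in detections:
            for det in detections[frame_id]:
                record = {
                    "frame_id": frame_id,
                    "class": det.class_label,
                    "bbox": [round(v, 3) for v in det.box.as_xywh()],
                    "confidence": round(det.confidence, 6),
                }
                fh.write(json.dumps(record) + "\n")


def read_detections(path: Union[str, Path]) -> dict[str, list[Detection]]:
    out: dict[str, list[Detection]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            det = Detection(
                class_label=record["class"],
                box=BoundingBox.from_xywh(*record["bbox"]),
                confidence=float(record["confidence"]),
            )
            out.setdefault(record["frame_id"], []).append(det)
    return out
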