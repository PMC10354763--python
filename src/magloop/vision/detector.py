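"""Classical droplet/particle detector.

Stands in for the trained neural detector behind the same interface: any
callable ``image -> list[Detection]`` can replace it.  Particles are found as
dark compact blobs; droplets as saturated color regions (reagent droplets) or
closed bright-rim contours filled in (transparent droplets).  Thresholds are
relative to the estimated background so the detector works across the full
25–1000 lux illumination range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, regionprops

from magloop.labels import CLASS_DROPLET, CLASS_PARTICLE
from magloop.vision.boxes import BoundingBox


@dataclass(frozen=True)
class Detection:
    class_label: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class DetectorParams:
    dark_margin: float = 15.0  # particles: below background minus this
    dark_ceiling: float = 60.0  # ...and never brighter than this absolute level
    rim_margin: float = 12.0  # transparent droplets: rim above background plus this
    chroma_threshold: float = 20.0  # colored droplets: max-min channel spread
    min_particle_area: int = 25
    max_particle_area: int = 4000
    min_droplet_area: int = 60


def _region_box(region, width: int, height: int) -> BoundingBox:
    y0, x0, y1, x1 = region.bbox
    return BoundingBox(float(x0), float(y0), float(min(x1, width)), float(min(y1, height)))


def detect(image: np.ndarray, params: DetectorParams = DetectorParams()) -> list[Detection]:
    """Detect droplets and particles in an H x W x 3 uint8 frame."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel image")
    img = image.astype(np.float64)
    gray = img @ np.array([0.2126, 0.7152, 0.0722])
    h, w = gray.shape
    bg = float(np.median(gray))

    chroma = img.max(axis=2) - img.min(axis=2)
    dark = (gray < min(bg - params.dark_margin, params.dark_ceiling)) & (chroma < params.chroma_threshold)
    bright_rim = (gray > bg + params.rim_margin) & (chroma < params.chroma_threshold)
    colored = chroma >= params.chroma_threshold

    detections: list[Detection] = []

    droplet_mask = binary_fill_holes(bright_rim | colored) | colored
    for region in regionprops(label(droplet_mask)):
        if region.area < params.min_droplet_area:
            continue
        box = _region_box(region, w, h)
        patch_chroma = float(np.mean(chroma[region.slice]))
        contrast = max(patch_chroma, params.rim_margin + 1.0)
        confidence = float(np.clip(0.5 + contrast / 255.0, 0.0, 1.0))
        detections.append(Detection(CLASS_DROPLET, box, confidence))

    for region in regionprops(label(dark), intensity_image=gray):
        if not params.min_particle_area <= region.area <= params.max_particle_area:
            continue
        box = _region_box(region, w, h)
        darkness = bg - float(region.intensity_mean)
        confidence = float(np.clip(0.5 + max(darkness, 0.0) / 255.0, 0.0, 1.0))
        detections.append(Detection(CLASS_PARTICLE, box, confidence))

    return detections
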