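"""Rasterize a platform state into an annotated frame.

Droplets are drawn as discs: transparent water droplets as a faint disc with a
brighter rim (deliberately low contrast), reagent droplets as a filled RGB
color.  Particle clusters are dark filled discs.  Annotations are the exact
geometric bounding boxes of the drawn objects (continuous px, clipped to the
image), so re-deriving boxes from the simulator state always matches them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import disk

from magloop.imaging.camera import CameraModel
from magloop.sim.state import PlatformState
from magloop.labels import CLASS_DROPLET, CLASS_PARTICLE
from magloop.vision.boxes import BoundingBox

#: Clusters below this volume (μl) are residuals: invisible and unannotated.
MIN_VISIBLE_CLUSTER_UL = 0.05

RIM_DELTA = 25  # rim intensity above background for transparent droplets
FILL_DELTA = 8  # interior intensity above background for transparent droplets
RIM_THICKNESS_PX = 2.0
PARTICLE_RGB = (20, 20, 20)


@dataclass(frozen=True)
class Annotation:
    class_label: str
    box: BoundingBox


@dataclass
class AnnotatedFrame:
    frame_id: str
    image: Optional[np.ndarray]  # H x W x 3 uint8, or None for annotation-only records
    annotations: list[Annotation]
    provenance: dict = field(default_factory=dict)


def _clipped_box(cx: float, cy: float, radius: float, width: int, height: int) -> Optional[BoundingBox]:
    x_min, x_max = max(cx - radius, 0.0), min(cx + radius, float(width))
    y_min, y_max = max(cy - radius, 0.0), min(cy + radius, float(height))
    if x_min >= x_max or y_min >= y_max:
        return None
    return BoundingBox(x_min, y_min, x_max, y_max)


def annotate(state: PlatformState, camera: CameraModel) -> list[Annotation]:
    """Ground-truth boxes of every visible object, without rasterizing."""
    out: list[Annotation] = []
    for droplet in state.droplets.values():
        cx, cy = camera.to_px(droplet.center)
        box = _clipped_box(cx, cy, droplet.footprint_radius * camera.pixels_per_mm, camera.image_width, camera.image_height)
        if box is not None:
            out.append(Annotation(CLASS_DROPLET, box))
    for cluster in state.clusters.values():
        if cluster.volume < MIN_VISIBLE_CLUSTER_UL:
            continue
        cx, cy = camera.to_px(cluster.center)
        box = _clipped_box(cx, cy, cluster.radius * camera.pixels_per_mm, camera.image_width, camera.image_height)
        if box is not None:
            out.append(Annotation(CLASS_PARTICLE, box))
    return out


def render(
    state: PlatformState,
    camera: CameraModel,
    frame_id: str = "frame",
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    provenance: Optional[dict] = None,
) -> AnnotatedFrame:
    """Draw the state under the camera's illumination. Pure: ``state`` is untouched."""
    h, w = camera.image_height, camera.image_width
    bg = camera.background_value()
    image = np.full((h, w, 3), bg, dtype=np.float64)
    shape = (h, w)

    for droplet in state.droplets.values():
        cx, cy = camera.to_px(droplet.center)
        r = droplet.footprint_radius * camera.pixels_per_mm
        rr, cc = disk((cy, cx), r, shape=shape)
        if droplet.color is not None:
            image[rr, cc] = droplet.color
        else:
            image[rr, cc] = min(bg + FILL_DELTA, 255)
            inner = max(r - RIM_THICKNESS_PX, 0.0)
            rim = np.zeros(shape, dtype=bool)
            rim[rr, cc] = True
            if inner > 0:
                rr_i, cc_i = disk((cy, cx), inner, shape=shape)
                rim[rr_i, cc_i] = False
            image[rim] = min(bg + RIM_DELTA, 255)

    for cluster in state.clusters.values():
        if cluster.volume < MIN_VISIBLE_CLUSTER_UL:
            continue
        cx, cy = camera.to_px(cluster.center)
        rr, cc = disk((cy, cx), cluster.radius * camera.pixels_per_mm, shape=shape)
        image[rr, cc] = PARTICLE_RGB

    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng for reproducibility")
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)

    frame = AnnotatedFrame(
        frame_id=frame_id,
        image=np.clip(image, 0, 255).astype(np.uint8),
        annotations=annotate(state, camera),
        provenance=dict(provenance or {}),
    )
    return frame
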