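"""Success criteria the feedback loop judges operations by.

* a droplet has reached its destination when its detected box center is within
  the tolerance (inclusive) of the target point;
* particle extraction succeeded when the particle and droplet boxes are
  disjoint (zero intersection area — touching edges count as disjoint under
  half-open intervals);
* droplet merging succeeded when the merged droplet's box grew by at least the
  growth threshold in BOTH width and height versus the still droplet's box.
"""

from __future__ import annotations

import math

from magloop.vision.boxes import BoundingBox


def at_destination(center: tuple[float, float], destination: tuple[float, float], tolerance: float) -> bool:
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    return math.dist(center, destination) <= tolerance


def extraction_succeeded(particle_box: BoundingBox, droplet_box: BoundingBox) -> bool:
    return particle_box.intersection_area(droplet_box) == 0.0


def merge_succeeded(before: BoundingBox, after: BoundingBox, growth: float) -> bool:
    if growth <= 0:
        raise ValueError(f"growth must be > 0, got {growth}")
    return (after.width - before.width >= growth) and (after.height - before.height >= growth)
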