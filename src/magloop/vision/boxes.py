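"""Axis-aligned bounding boxes as half-open pixel intervals.

Areas are computed in continuous coordinates (``width = x_max - x_min``), so a
box covering pixels [0, 10) x [0, 10) has area 100.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("box coordinates must be non-negative")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def intersection_area(self, other: "BoundingBox") -> float:
        ox = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        oy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return ox * oy if (ox > 0 and oy > 0) else 0.0

    def contains_point(self, point: tuple[float, float]) -> bool:
        return self.x_min <= point[0] < self.x_max and self.y_min <= point[1] < self.y_max

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and other.x_max <= self.x_max
            and other.y_max <= self.y_max
        )

    def as_xywh(self) -> list[float]:
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        return cls(x, y, x + w, y + h)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    if a.area <= 0 or b.area <= 0:
        raise ValueError("IoU undefined for zero-area boxes")
    inter = a.intersection_area(b)
    return inter / (a.area + b.area - inter)
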