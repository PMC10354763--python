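"""Pinhole-free top-down camera: a linear mm→px map plus an illumination model."""

from __future__ import annotations

from dataclasses import dataclass

LUX_MIN = 25.0
LUX_MAX = 1000.0


@dataclass(frozen=True)
class CameraModel:
    """Maps world millimeters to image pixels and lux to background brightness.

    The default 10 px/mm over a 40 x 40 mm field of view gives 400 x 400 px
    frames; every pixel threshold downstream (10 px tolerance, 3 px growth,
    20 px overshoot) is interpreted in this space, origin top-left, y downward.
    """

    pixels_per_mm: float = 10.0
    image_width: int = 400
    image_height: int = 400
    illumination: float = 500.0

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise ValueError(f"pixels_per_mm must be > 0, got {self.pixels_per_mm}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if not LUX_MIN <= self.illumination <= LUX_MAX:
            raise ValueError(f"illumination must be within [{LUX_MIN}, {LUX_MAX}] lux, got {self.illumination}")

    @classmethod
    def for_field(cls, width_mm: float, height_mm: float, pixels_per_mm: float = 10.0, illumination: float = 500.0):
        return cls(
            pixels_per_mm=pixels_per_mm,
            image_width=int(round(width_mm * pixels_per_mm)),
            image_height=int(round(height_mm * pixels_per_mm)),
            illumination=illumination,
        )

    @property
    def field_mm(self) -> tuple[float, float]:
        return (self.image_width / self.pixels_per_mm, self.image_height / self.pixels_per_mm)

    def background_value(self) -> int:
        """Background gray level: a documented monotone map of illumination."""
        g = 40.0 + 180.0 * (self.illumination - LUX_MIN) / (LUX_MAX - LUX_MIN)
        return int(round(min(max(g, 0.0), 255.0)))

    def to_px(self, point_mm: tuple[float, float]) -> tuple[float, float]:
        return (point_mm[0] * self.pixels_per_mm, point_mm[1] * self.pixels_per_mm)

    def to_mm(self, point_px: tuple[float, float]) -> tuple[float, float]:
        return (point_px[0] / self.pixels_per_mm, point_px[1] / self.pixels_per_mm)
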