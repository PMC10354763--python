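"""Colorimetric readout: droplet color sampling and red vs yellow/orange calls.

A carbapenem-hydrolyzing reaction drops the pH and shifts the indicator from
red toward yellow/orange; the call is made in hue–saturation space.  The hue
bounds quantify that qualitative rule and are configurable.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np

from magloop.vision.boxes import BoundingBox

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ColorClassifierConfig:
    positive_hue: tuple[float, float] = (20.0, 90.0)  # yellow/orange, degrees
    negative_hue: tuple[float, float] = (340.0, 20.0)  # red, wrap-around
    saturation_floor: float = 0.2


def classify_color(rgb: tuple[float, float, float], config: ColorClassifierConfig = ColorClassifierConfig()) -> str:
    """Classify an RGB triple as positive (yellow/orange), negative (red) or indeterminate."""
    if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
        raise ValueError(f"RGB components must be in [0, 255], got {rgb}")
    h, s, _ = colorsys.rgb_to_hsv(rgb[0] / 255.0, rgb[1] / 255.0, rgb[2] / 255.0)
    hue = h * 360.0
    if s < config.saturation_floor:
        return INDETERMINATE
    lo, hi = config.positive_hue
    if lo <= hue <= hi:
        return POSITIVE
    nlo, nhi = config.negative_hue
    if hue >= nlo or hue < nhi:  # wrap-around red band
        return NEGATIVE
    return INDETERMINATE


def read_droplet_color(frame: np.ndarray, droplet_box: BoundingBox) -> tuple[float, float, float]:
    """Mean RGB over the central 50%-area sub-box (avoids rim pixels)."""
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    h, w = frame.shape[:2]
    if droplet_box.x_min < 0 or droplet_box.y_min < 0 or droplet_box.x_max > w or droplet_box.y_max > h:
        raise ValueError(f"box {droplet_box} outside frame {w}x{h}")
    shrink = (1.0 - 1.0 / np.sqrt(2.0)) / 2.0  # keep the central half of the area
    x0 = int(np.floor(droplet_box.x_min + shrink * droplet_box.width))
    x1 = int(np.ceil(droplet_box.x_max - shrink * droplet_box.width))
    y0 = int(np.floor(droplet_box.y_min + shrink * droplet_box.height))
    y1 = int(np.ceil(droplet_box.y_max - shrink * droplet_box.height))
    patch = frame[y0:y1, x0:x1].astype(np.float64)
    mean = patch.reshape(-1, 3).mean(axis=0)
    return (float(mean[0]), float(mean[1]), float(mean[2]))
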