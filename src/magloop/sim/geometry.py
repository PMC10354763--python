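"""Footprint geometry of sessile droplets and particle clusters.

Droplets on the hydrophobic substrate are modeled as spherical caps with a
fixed contact angle; only the circular 2-D footprint matters for overlap,
anchoring and rendering.  Particle clusters are modeled as hemispherical piles.
All volumes are in microliters (= mm^3), lengths in millimeters.
"""

from __future__ import annotations

import math

#: Contact angle of a water droplet on the Teflon-coated substrate, degrees.
DEFAULT_CONTACT_ANGLE_DEG = 120.0


def cap_footprint_radius(volume_ul: float, contact_angle_deg: float = DEFAULT_CONTACT_ANGLE_DEG) -> float:
    """Radius (mm) of the circular footprint of a spherical-cap droplet.

    For a cap cut from a sphere of radius ``R`` at contact angle ``theta`` the
    volume is ``V = (pi/3) R^3 (1 - cos t)^2 (2 + cos t)`` and the footprint
    radius is ``R sin t``.
    """
    if volume_ul <= 0:
        raise ValueError(f"droplet volume must be positive, got {volume_ul}")
    if not 0 < contact_angle_deg < 180:
        raise ValueError(f"contact angle must be in (0, 180) degrees, got {contact_angle_deg}")
    t = math.radians(contact_angle_deg)
    shape = (1.0 - math.cos(t)) ** 2 * (2.0 + math.cos(t))
    sphere_radius = (3.0 * volume_ul / (math.pi * shape)) ** (1.0 / 3.0)
    return sphere_radius * math.sin(t)


def cluster_radius(volume_ul: float) -> float:
    """Radius (mm) of a hemispherical particle pile of the given volume."""
    if volume_ul <= 0:
        raise ValueError(f"cluster volume must be positive, got {volume_ul}")
    return (3.0 * volume_ul / (2.0 * math.pi)) ** (1.0 / 3.0)


def distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def advance_toward(
    position: tuple[float, float], target: tuple[float, float], max_travel: float
) -> tuple[float, float]:
    """Move ``position`` toward ``target`` by at most ``max_travel`` mm."""
    d = distance(position, target)
    if d <= max_travel or d == 0.0:
        return (target[0], target[1])
    f = max_travel / d
    return (position[0] + f * (target[0] - position[0]), position[1] + f * (target[1] - position[1]))
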