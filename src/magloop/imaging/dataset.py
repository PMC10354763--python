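"""Synthetic annotated-frame generator covering six scene categories.

Categories mirror the kinds of frames the feedback controller must cope with:

* ``pd_ratio`` — transparent droplets with a wide range of particle/droplet
  volume ratios;
* ``aspect_ratio`` — frames of differing aspect ratios, droplets with or
  without particles;
* ``boundary_motion`` — particle clusters caught halfway in/out of droplets;
* ``illumination`` — scenes at the extremes of the 25–1000 lux range;
* ``carba_colored`` — red and yellow/orange reagent droplets;
* ``bca_colored`` — green/purple reagent droplets.

Generation is fully deterministic given the seed (one RNG stream drives
everything), so the same seed yields bit-identical frames.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from magloop.imaging.camera import CameraModel
from magloop.imaging.render import AnnotatedFrame, annotate, render
from magloop.sim.geometry import cap_footprint_radius, cluster_radius, distance
from magloop.sim.state import DropletState, ParticleClusterState, PlatformState

CATEGORIES = (
    "pd_ratio",
    "aspect_ratio",
    "boundary_motion",
    "illumination",
    "carba_colored",
    "bca_colored",
)

CARBA_PALETTE = [(200, 45, 50), (215, 60, 40), (235, 190, 45), (230, 150, 60)]
BCA_PALETTE = [(110, 190, 130), (90, 160, 110), (120, 80, 160), (100, 90, 170)]


class DatasetConfigError(ValueError):
    """Raised for unknown category tokens or invalid generation parameters."""


def _sample_lux(rng: np.random.Generator, category: str) -> float:
    if category == "illumination":
        # emphasize the extremes of the operating range
        return float(rng.choice([25.0, 1000.0, rng.uniform(25.0, 1000.0)]))
    return float(rng.uniform(25.0, 1000.0))


def _place_droplets(rng: np.random.Generator, field_mm, n, volumes, margin=3.0):
    """Rejection-sample non-overlapping droplet centers."""
    placed: list[tuple[tuple[float, float], float]] = []
    for volume in volumes[:n]:
        r = cap_footprint_radius(volume)
        for _ in range(200):
            c = (
                float(rng.uniform(margin + r, field_mm[0] - margin - r)),
                float(rng.uniform(margin + r, field_mm[1] - margin - r)),
            )
            if all(distance(c, pc) > r + pr + 1.0 for pc, pr in ((p, cap_footprint_radius(v)) for p, v in placed)):
                placed.append((c, volume))
                break
    return placed


def _scene(rng: np.random.Generator, category: str, camera: CameraModel) -> PlatformState:
    field = camera.field_mm
    state = PlatformState(bounds=field)
    n = int(rng.integers(1, 4))
    volumes = [float(rng.uniform(2.0, 20.0)) for _ in range(n)]
    colored = category in ("carba_colored", "bca_colored")
    palette = CARBA_PALETTE if category == "carba_colored" else BCA_PALETTE
    for i, (center, volume) in enumerate(_place_droplets(rng, field, n, volumes)):
        color = palette[int(rng.integers(0, len(palette)))] if colored else None
        droplet = DropletState(id=f"d{i}", center=center, volume=volume, color=color)
        state.add_droplet(droplet)
        want_particles = category != "aspect_ratio" or bool(rng.integers(0, 2))
        if not want_particles:
            continue
        if category == "pd_ratio":
            pv = float(volume * rng.uniform(0.02, 0.15))
        else:
            pv = float(rng.uniform(0.2, 1.5))
        # the particle pile must fit visibly inside the droplet footprint
        max_pv = (2.0 * np.pi / 3.0) * (0.7 * droplet.footprint_radius) ** 3
        pv = min(pv, max_pv)
        if category == "boundary_motion":
            # cluster halfway across the droplet boundary, or just outside
            direction = rng.uniform(0, 2 * np.pi)
            offset = droplet.footprint_radius * float(rng.uniform(0.8, 1.6))
            c = state.clamp((center[0] + offset * np.cos(direction), center[1] + offset * np.sin(direction)))
            host = droplet.id if droplet.contains(c) else None
            cluster = ParticleClusterState(id=f"p{i}", center=c, volume=pv, host_droplet_id=host)
        else:
            cluster = ParticleClusterState(id=f"p{i}", center=center, volume=pv, host_droplet_id=droplet.id)
        droplet.particle_volume_inside = pv if cluster.host_droplet_id else 0.0
        state.add_cluster(cluster)
    return state


def generate_dataset(
    n_frames: int,
    seed: int,
    categories: Optional[Sequence[str]] = None,
    camera: Optional[CameraModel] = None,
    keep_images: bool = True,
    noise_sigma: float = 0.0,
) -> list[AnnotatedFrame]:
    """Generate ``n_frames`` annotated frames cycling through the categories.

    With ``keep_images=False`` only the annotation records are produced
    (``frame.image is None``), which is much cheaper for split/count workflows.
    """
    if n_frames <= 0:
        raise DatasetConfigError(f"n_frames must be > 0, got {n_frames}")
    categories = tuple(categories) if categories else CATEGORIES
    for token in categories:
        if token not in CATEGORIES:
            raise DatasetConfigError(f"unknown category token {token!r}; expected one of {CATEGORIES}")
    base = camera or CameraModel()
    rng = np.random.default_rng(seed)
    frames: list[AnnotatedFrame] = []
    for i in range(n_frames):
        category = categories[i % len(categories)]
        cam = base
        if category == "aspect_ratio":
            h_mm = float(rng.choice([24.0, 30.0, base.field_mm[1]]))
            cam = CameraModel(
                pixels_per_mm=base.pixels_per_mm,
                image_width=base.image_width,
                image_height=int(round(h_mm * base.pixels_per_mm)),
                illumination=base.illumination,
            )
        cam = CameraModel(
            pixels_per_mm=cam.pixels_per_mm,
            image_width=cam.image_width,
            image_height=cam.image_height,
            illumination=_sample_lux(rng, category),
        )
        state = _scene(rng, category, cam)
        frame_id = f"frame_{i:05d}_{category}"
        provenance = {"category": category, "seed": seed, "index": i, "illumination": cam.illumination}
        if keep_images:
            frame = render(state, cam, frame_id=frame_id, noise_sigma=noise_sigma, rng=rng if noise_sigma > 0 else None, provenance=provenance)
        else:
            frame = AnnotatedFrame(frame_id=frame_id, image=None, annotations=annotate(state, cam), provenance=provenance)
        frames.append(frame)
    return frames
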