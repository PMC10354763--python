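"""The four closed-loop droplet operations with failure rectification.

Every operation follows the same shape: act through the actuation interface,
re-detect through the detection interface, judge the outcome with the pixel
criteria, and on failure return the control point to the particles and retry
with an adjusted speed — lower for transport (magnet disengagement), higher
for extraction (surface-tension retention).  The controller never touches
simulator ground truth; it sees only :class:`~magloop.vision.detector.Detection`
objects, so a corrupted detector degrades it to ``failed``/``aborted``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from magloop.control.adapters import Actuation, Eyes
from magloop.control.config import OperationConfig
from magloop.control.criteria import at_destination, extraction_succeeded, merge_succeeded
from magloop.imaging.render import CLASS_DROPLET, CLASS_PARTICLE
from magloop.vision.detector import Detection

Vec = tuple[float, float]

STATUS_SUCCESS = "success"
STATUS_FAILED = "failed"
STATUS_ABORTED = "aborted"

COMPASS = {"EAST": (1.0, 0.0), "WEST": (-1.0, 0.0), "NORTH": (0.0, -1.0), "SOUTH": (0.0, 1.0)}


class PreconditionError(RuntimeError):
    """The detector snapshot does not satisfy the operation's precondition."""


@dataclass(frozen=True)
class Attempt:
    stage: str  # which destination / leg this attempt belongs to
    speed: float  # commanded speed, mm/s (nan for no-motion checks)
    outcome: str  # "success" | "retry" | "aborted"
    snapshot: str  # detector snapshot id (simulated capture time)


@dataclass
class OperationResult:
    status: str
    retries: int
    attempts: list[Attempt] = field(default_factory=list)
    final_state_summary: str = ""

    @property
    def ok(self) -> bool:
        return self.status == STATUS_SUCCESS


# ---------------------------------------------------------------------------
# detection bookkeeping helpers (all geometry in pixels)


def _by_class(dets: Sequence[Detection], label: str) -> list[Detection]:
    return [d for d in dets if d.class_label == label]


def _nearest(dets: Sequence[Detection], point: Optional[Vec]) -> Optional[Detection]:
    if not dets:
        return None
    if point is None:
        return dets[0]
    return min(dets, key=lambda d: math.dist(d.box.center, point))


def _droplet_of(dets: Sequence[Detection], point: Vec) -> Optional[Detection]:
    """Droplet detection containing the point; smallest such box wins."""
    containing = [d for d in _by_class(dets, CLASS_DROPLET) if d.box.contains_point(point)]
    if containing:
        return min(containing, key=lambda d: d.box.area)
    return _nearest(_by_class(dets, CLASS_DROPLET), point)


def _snapshot(world) -> str:
    return f"t={getattr(world, 'time', 0.0):.2f}s"


def _clamp_px(world, point: Vec) -> Vec:
    cam = getattr(world, "camera", None)
    if cam is None:
        return point
    return (min(max(point[0], 0.0), cam.image_width - 1.0), min(max(point[1], 0.0), cam.image_height - 1.0))


def _go_to_particles(world: Actuation, point: Vec, config: OperationConfig) -> None:
    """Return the CP to the detected particle centroid with the field off."""
    world.set_magnet(False)
    world.move_to(point, config.default_speed)
    world.set_magnet(True)


# ---------------------------------------------------------------------------
# droplet transport


def transport(
    destinations: Sequence[Vec],
    config: OperationConfig,
    world: Actuation,
    eyes: Eyes,
    particle_hint: Optional[Vec] = None,
    tolerance: Optional[float] = None,
) -> OperationResult:
    """Drag the particle-bearing droplet through the destinations in order.

    Each destination is approached with the overshoot maneuver (beyond the
    destination along +y by ``config.overshoot`` px, then back).  A failed
    arrival check (magnet disengagement) triggers a retry at
    ``retry_slowdown`` times the previous speed, restarting from wherever the
    particles currently are.
    """
    if not destinations:
        raise ValueError("destinations must be non-empty")
    tol = tolerance if tolerance is not None else config.destination_tolerance
    dets = eyes.capture()
    particle = _nearest(_by_class(dets, CLASS_PARTICLE), particle_hint)
    if particle is None:
        raise PreconditionError("no particle cluster detected")
    p_pos = particle.box.center

    attempts: list[Attempt] = []
    total_retries = 0
    for di, dest in enumerate(destinations):
        speed = config.default_speed
        arrived = False
        for _ in range(config.max_retries + 1):
            dets = eyes.capture()
            particle = _nearest(_by_class(dets, CLASS_PARTICLE), p_pos)
            if particle is None:
                world.set_magnet(False)
                return OperationResult(STATUS_ABORTED, total_retries, attempts, "particles lost from detections")
            p_pos = particle.box.center
            droplet = _droplet_of(dets, p_pos)
            if droplet is None:
                world.set_magnet(False)
                return OperationResult(STATUS_ABORTED, total_retries, attempts, "droplet lost from detections")
            if at_destination(droplet.box.center, dest, tol):
                attempts.append(Attempt(f"dest{di}", math.nan, STATUS_SUCCESS, _snapshot(world)))
                arrived = True
                break

            _go_to_particles(world, p_pos, config)
            over = _clamp_px(world, (dest[0], dest[1] + config.overshoot))
            world.move_to(over, speed)
            world.move_to(dest, speed)
            world.settle()

            dets = eyes.capture()
            particle = _nearest(_by_class(dets, CLASS_PARTICLE), dest)
            droplet = _droplet_of(dets, dest) if particle is None else _droplet_of(dets, particle.box.center)
            ok = droplet is not None and at_destination(droplet.box.center, dest, tol)
            attempts.append(Attempt(f"dest{di}", speed, STATUS_SUCCESS if ok else "retry", _snapshot(world)))
            if particle is not None:
                p_pos = particle.box.center
            if ok:
                arrived = True
                break
            total_retries += 1
            speed *= config.retry_slowdown
        if not arrived:
            world.set_magnet(False)
            return OperationResult(
                STATUS_FAILED, config.max_retries, attempts, f"destination {di} unreached after retries"
            )
    world.set_magnet(False)
    return OperationResult(STATUS_SUCCESS, total_retries, attempts, "all destinations confirmed")


# ---------------------------------------------------------------------------
# particle extraction


def extract(
    direction: str,
    travel: float,
    config: OperationConfig,
    world: Actuation,
    eyes: Eyes,
    particle_hint: Optional[Vec] = None,
) -> OperationResult:
    """Pull the particle cluster out of its droplet along a compass direction.

    Starts at ``retry_speedup x default_speed`` and raises the speed by the
    same factor after every failed (still-overlapping) check.  No overshoot is
    applied.  Compass directions are image-frame: NORTH is -y (up).
    """
    if direction not in COMPASS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {sorted(COMPASS)}")
    if travel <= 0:
        raise ValueError(f"travel must be > 0, got {travel}")
    dets = eyes.capture()
    particle = _nearest(_by_class(dets, CLASS_PARTICLE), particle_hint)
    if particle is None:
        raise PreconditionError("no particle cluster detected")
    droplets = _by_class(dets, CLASS_DROPLET)
    if not droplets:
        raise PreconditionError("no droplet detected")
    p_pos = particle.box.center
    host = next((d for d in droplets if d.box.intersection_area(particle.box) > 0), None)
    if host is None:
        return OperationResult(
            STATUS_SUCCESS, 0, [Attempt("check", math.nan, STATUS_SUCCESS, _snapshot(world))],
            "particles already outside the droplet",
        )
    droplet_pos = host.box.center

    vec = COMPASS[direction]
    speed = config.retry_speedup * config.default_speed
    attempts: list[Attempt] = []
    for attempt_index in range(config.max_retries + 1):
        _go_to_particles(world, p_pos, config)
        target = _clamp_px(world, (p_pos[0] + vec[0] * travel, p_pos[1] + vec[1] * travel))
        world.move_to(target, speed)
        world.settle()

        dets = eyes.capture()
        particle = _nearest(_by_class(dets, CLASS_PARTICLE), target)
        droplet = _nearest(_by_class(dets, CLASS_DROPLET), droplet_pos)
        if particle is None or droplet is None:
            world.set_magnet(False)
            return OperationResult(STATUS_ABORTED, attempt_index, attempts, "object lost from detections")
        ok = extraction_succeeded(particle.box, droplet.box)
        attempts.append(Attempt("extract", speed, STATUS_SUCCESS if ok else "retry", _snapshot(world)))
        if ok:
            world.set_magnet(False)
            return OperationResult(STATUS_SUCCESS, attempt_index, attempts, "particle and droplet boxes disjoint")
        p_pos = particle.box.center
        droplet_pos = droplet.box.center
        speed *= config.retry_speedup
    world.set_magnet(False)
    return OperationResult(STATUS_FAILED, config.max_retries, attempts, "extraction retries exhausted")


# ---------------------------------------------------------------------------
# droplet merging


def merge(
    config: OperationConfig,
    world: Actuation,
    eyes: Eyes,
    moving_hint: Optional[Vec] = None,
    still_hint: Optional[Vec] = None,
) -> OperationResult:
    """Transport the particle-bearing droplet onto the still droplet and verify
    bounding-box growth in both dimensions."""
    dets = eyes.capture()
    particles = _by_class(dets, CLASS_PARTICLE)
    droplets = _by_class(dets, CLASS_DROPLET)
    if not particles:
        raise PreconditionError("no particle cluster detected")
    bearing = [d for d in droplets if any(d.box.contains_point(p.box.center) for p in particles)]
    stills = [d for d in droplets if d not in bearing]
    if not bearing:
        raise PreconditionError("neither droplet contains particles")
    moving = _nearest(bearing, moving_hint)
    still = _nearest(stills, still_hint)
    if still is None:
        if len(droplets) >= 2:
            raise PreconditionError("both droplets contain particles")
        raise PreconditionError("still droplet missing from detections")
    if still_hint is not None and any(b.box.contains_point(still_hint) for b in bearing):
        raise PreconditionError("both droplets contain particles")

    before = still.box
    dest = before.center
    particle = _nearest(particles, moving.box.center)
    p_pos = particle.box.center

    attempts: list[Attempt] = []
    retries = 0
    for attempt_index in range(config.max_retries + 1):
        inner = transport([dest], config, world, eyes, particle_hint=p_pos)
        attempts.extend(inner.attempts)
        retries += inner.retries
        if inner.status != STATUS_SUCCESS:
            return OperationResult(inner.status, retries, attempts, f"inner transport {inner.status}")
        dets = eyes.capture()
        particle = _nearest(_by_class(dets, CLASS_PARTICLE), dest)
        if particle is None:
            return OperationResult(STATUS_ABORTED, retries, attempts, "particles lost from detections")
        p_pos = particle.box.center
        merged = _droplet_of(dets, p_pos)
        ok = merged is not None and merge_succeeded(before, merged.box, config.merge_growth)
        attempts.append(Attempt("merge-check", math.nan, STATUS_SUCCESS if ok else "retry", _snapshot(world)))
        if ok:
            return OperationResult(STATUS_SUCCESS, retries, attempts, "merged box grew in both dimensions")
        retries += 1
    return OperationResult(STATUS_FAILED, config.max_retries, attempts, "merge retries exhausted")


# ---------------------------------------------------------------------------
# passive mixing


def mix(
    loops: int,
    arm_length: float,
    config: OperationConfig,
    world: Actuation,
    eyes: Eyes,
    waypoints: Optional[Sequence[Vec]] = None,
    particle_hint: Optional[Vec] = None,
) -> OperationResult:
    """Loop the droplet along a cross-shaped path centered on the particles.

    Each leg is a full transport with rectification; after each arm the
    droplet returns to the center.  ``waypoints`` replaces the cross with a
    custom per-loop path.
    """
    if loops < 1:
        raise ValueError(f"loops must be >= 1, got {loops}")
    if arm_length <= 0 and not waypoints:
        raise ValueError(f"arm_length must be > 0, got {arm_length}")
    dets = eyes.capture()
    particle = _nearest(_by_class(dets, CLASS_PARTICLE), particle_hint)
    if particle is None:
        raise PreconditionError("no particle cluster detected")
    cx, cy = particle.box.center

    if waypoints:
        path = list(waypoints)
    else:
        path = [
            (cx + arm_length, cy), (cx, cy),
            (cx - arm_length, cy), (cx, cy),
            (cx, cy - arm_length), (cx, cy),
            (cx, cy + arm_length), (cx, cy),
        ]

    attempts: list[Attempt] = []
    retries = 0
    p_pos = (cx, cy)
    for loop_index in range(loops):
        for leg_index, point in enumerate(path):
            leg = transport([point], config, world, eyes, particle_hint=p_pos)
            attempts.extend(
                Attempt(f"loop{loop_index}-leg{leg_index}", a.speed, a.outcome, a.snapshot) for a in leg.attempts
            )
            retries += leg.retries
            if leg.status != STATUS_SUCCESS:
                return OperationResult(leg.status, retries, attempts, f"leg {leg_index} of loop {loop_index} {leg.status}")
            dets = eyes.capture()
            particle = _nearest(_by_class(dets, CLASS_PARTICLE), point)
            if particle is not None:
                p_pos = particle.box.center
    return OperationResult(STATUS_SUCCESS, retries, attempts, f"{loops} mixing loops completed")
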