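"""State-transition operations: magnet step, contact merging, SET anchoring.

All operations are pure: they return a new :class:`PlatformState` and never
mutate their input.  There is no randomness anywhere in the simulator, so
identical command sequences yield identical trajectories.
"""

from __future__ import annotations

import math

from magloop.sim.geometry import advance_toward, distance
from magloop.sim.model import EngagementModel, disengagement_speed, release_speed
from magloop.sim.state import DropletState, PlatformState, Vec


def step(
    state: PlatformState,
    target: Vec,
    speed: float,
    dt: float,
    model: EngagementModel,
) -> PlatformState:
    """Advance the magnet toward ``target`` for one time slice and move objects.

    The control point advances by ``min(speed * dt, remaining distance)``; the
    physical magnet follows it through a first-order delay of time constant
    ``magnet.lag``.  Each cluster within the magnet capture radius then reacts
    according to the engagement regime selected by ``speed``:

    * ``speed > disengagement_speed`` — the magnet outruns the cluster; neither
      the cluster nor its droplet moves.
    * hosted cluster, ``speed >= release threshold`` — extraction: the cluster
      tracks the magnet, and once it crosses the droplet footprint it detaches
      (a small residual fraction of particles stays in the droplet).
    * hosted cluster below the release threshold — transport: cluster and
      droplet translate together (an anchored droplet stays pinned and clamps
      the cluster inside its footprint instead).
    * free cluster — tracks the magnet; if it ends the slice inside a droplet
      footprint it is captured by (re-hosted in) that droplet.

    Liquid volumes are never changed by this operation.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if speed < 0:
        raise ValueError(f"speed must be >= 0, got {speed}")
    if not state.in_bounds(target):
        raise ValueError(f"target {target} outside bounds {state.bounds}")

    s = state.copy()
    s.time = state.time + dt
    magnet = s.magnet
    old_position = magnet.position

    magnet.cp = advance_toward(magnet.cp, target, speed * dt)
    if magnet.lag > 0:
        alpha = 1.0 - math.exp(-dt / magnet.lag)
        magnet.position = (
            magnet.position[0] + alpha * (magnet.cp[0] - magnet.position[0]),
            magnet.position[1] + alpha * (magnet.cp[1] - magnet.position[1]),
        )
    else:
        magnet.position = magnet.cp
    magnet.speed = speed

    if not magnet.engaged:
        return s

    for cluster in s.clusters.values():
        if distance(cluster.center, old_position) > magnet.capture_radius:
            continue  # out of the field's reach; requires an explicit return move
        if speed > disengagement_speed(model, cluster.volume, magnet.power_level):
            continue  # magnet outruns the particles: nothing moves

        host = s.droplets.get(cluster.host_droplet_id) if cluster.host_droplet_id else None
        if host is None:
            cluster.center = magnet.position
            _maybe_rehost(s, cluster)
            continue

        anchored = host.anchored_set_id is not None
        threshold = release_speed(model, cluster.volume, anchored, magnet.power_level)
        if speed >= threshold:
            # extraction regime: droplet stays, cluster crosses the boundary
            cluster.center = magnet.position
            if distance(cluster.center, host.center) > host.footprint_radius:
                _detach(model, cluster, host)
        elif anchored:
            # pinned droplet: cluster is clamped inside the footprint
            cluster.center = _clamp_inside(magnet.position, host.center, host.footprint_radius)
        else:
            displacement = (magnet.position[0] - cluster.center[0], magnet.position[1] - cluster.center[1])
            cluster.center = magnet.position
            moved = (host.center[0] + displacement[0], host.center[1] + displacement[1])
            # capillary recentering: the droplet relaxes onto the particle pile
            lam = 1.0 - math.exp(-dt / model.recenter_tau)
            host.center = s.clamp(
                (moved[0] + lam * (cluster.center[0] - moved[0]), moved[1] + lam * (cluster.center[1] - moved[1]))
            )
    return s


def contact_merge(state: PlatformState) -> PlatformState:
    """Coalesce every pair of droplets with overlapping footprints.

    The merged droplet keeps the id of the larger-volume parent (ties: first in
    insertion order), carries the summed liquid and particle volumes, sits at
    the volume-weighted centroid, and blends the RGB color volume-weighted over
    the colored parents.  Idempotent once no footprints overlap.
    """
    s = state.copy()
    merged_any = True
    while merged_any:
        merged_any = False
        ids = list(s.droplets)
        for i, a_id in enumerate(ids):
            for b_id in ids[i + 1 :]:
                a, b = s.droplets[a_id], s.droplets[b_id]
                if distance(a.center, b.center) < a.footprint_radius + b.footprint_radius:
                    _merge_pair(s, a, b)
                    merged_any = True
                    break
            if merged_any:
                break
    return s


def anchor_check(state: PlatformState) -> PlatformState:
    """Anchor (and center) droplets whose center falls within a SET radius.

    Anchoring is sticky: it is only released by an explicit de-anchor, which no
    closed-loop operation performs — droplets stay at their traps.
    """
    s = state.copy()
    for droplet in s.droplets.values():
        if droplet.anchored_set_id is not None:
            continue
        for trap in s.sets.values():
            if distance(droplet.center, trap.center) <= trap.radius:
                droplet.anchored_set_id = trap.id
                droplet.center = trap.center  # hydrophilic patch self-centers the droplet
                break
    return s


def _detach(model: EngagementModel, cluster, host: DropletState) -> None:
    residual = model.residual_fraction * cluster.volume
    cluster.volume -= residual
    host.particle_volume_inside = max(host.particle_volume_inside - cluster.volume - residual, 0.0) + residual
    cluster.host_droplet_id = None


def _maybe_rehost(state: PlatformState, cluster) -> None:
    for droplet in state.droplets.values():
        if droplet.contains(cluster.center):
            cluster.host_droplet_id = droplet.id
            droplet.particle_volume_inside += cluster.volume
            break


def _clamp_inside(point: Vec, center: Vec, radius: float) -> Vec:
    d = distance(point, center)
    if d <= radius:
        return point
    f = radius / d
    return (center[0] + f * (point[0] - center[0]), center[1] + f * (point[1] - center[1]))


def _merge_pair(state: PlatformState, a: DropletState, b: DropletState) -> None:
    keep, drop = (b, a) if b.volume > a.volume else (a, b)
    total = keep.volume + drop.volume
    center = (
        (keep.center[0] * keep.volume + drop.center[0] * drop.volume) / total,
        (keep.center[1] * keep.volume + drop.center[1] * drop.volume) / total,
    )
    colored = [(d.color, d.volume) for d in (keep, drop) if d.color is not None]
    if colored:
        cv = sum(v for _, v in colored)
        color = tuple(int(round(sum(c[i] * v for c, v in colored) / cv)) for i in range(3))
    else:
        color = None
    keep.center = state.clamp(center)
    keep.volume = total
    keep.particle_volume_inside += drop.particle_volume_inside
    keep.color = color
    keep.anchored_set_id = keep.anchored_set_id or drop.anchored_set_id
    for cluster in state.clusters.values():
        if cluster.host_droplet_id == drop.id:
            cluster.host_droplet_id = keep.id
    del state.droplets[drop.id]
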