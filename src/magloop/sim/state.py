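"""Domain state of the simulated platform."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from magloop.sim.geometry import cap_footprint_radius, cluster_radius, distance
from magloop.sim.model import POWER_DEFAULT, POWER_LEVELS

Vec = tuple[float, float]

#: XY stage stroke per axis, mm.
STAGE_STROKE_MM = 50.0


@dataclass
class DropletState:
    """A sessile droplet.

    ``color`` is an RGB triple for reagent-colored droplets or ``None`` for a
    transparent water droplet.  ``particle_volume_inside`` tracks the particle
    volume currently carried by the droplet (hosted clusters plus residuals);
    the particle/droplet ratio is ``particle_volume_inside / volume``.
    """

    id: str
    center: Vec
    volume: float
    particle_volume_inside: float = 0.0
    color: Optional[tuple[int, int, int]] = None
    anchored_set_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"droplet {self.id}: volume must be > 0, got {self.volume}")
        if self.particle_volume_inside < 0:
            raise ValueError(f"droplet {self.id}: particle_volume_inside must be >= 0")
        if self.color is not None:
            self.color = tuple(int(c) for c in self.color)  # type: ignore[assignment]
            if len(self.color) != 3 or any(not 0 <= c <= 255 for c in self.color):
                raise ValueError(f"droplet {self.id}: color must be an RGB triple in [0, 255]")

    @property
    def footprint_radius(self) -> float:
        return cap_footprint_radius(self.volume)

    def pd_ratio(self) -> float:
        return self.particle_volume_inside / self.volume

    def contains(self, point: Vec) -> bool:
        return distance(self.center, point) <= self.footprint_radius


@dataclass
class ParticleClusterState:
    """A cluster of magnetic particles, possibly sitting inside a droplet."""

    id: str
    center: Vec
    volume: float
    host_droplet_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"cluster {self.id}: volume must be > 0, got {self.volume}")

    @property
    def radius(self) -> float:
        return cluster_radius(self.volume)


@dataclass
class MagnetState:
    """Electromagnet under the substrate, tracking the software control point.

    ``position`` is the physical magnet location; ``cp`` is the control point
    it follows.  With ``lag == 0`` (the test default) they coincide; a positive
    lag applies a first-order delay, mimicking the ~1 s hardware response.
    """

    position: Vec = (2.0, 2.0)
    engaged: bool = False
    speed: float = 0.0
    power_level: str = POWER_DEFAULT
    lag: float = 0.0
    cp: Optional[Vec] = None
    capture_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError(f"magnet speed must be >= 0, got {self.speed}")
        if self.power_level not in POWER_LEVELS:
            raise ValueError(f"unknown power level {self.power_level!r}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        for axis in self.position:
            if not 0 <= axis <= STAGE_STROKE_MM:
                raise ValueError(f"magnet position {self.position} outside stage stroke 0–{STAGE_STROKE_MM} mm")
        if self.cp is None:
            self.cp = self.position


@dataclass
class SurfaceEnergyTrap:
    """A locally hydrophilic patch that pins (and centers) a droplet."""

    id: str
    center: Vec
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"SET {self.id}: radius must be > 0, got {self.radius}")


@dataclass
class PlatformState:
    """The full simulated world: droplets, clusters, magnet, SETs, clock.

    Object ids are unique by construction (dict keys).  Total liquid volume is
    conserved by every operation except explicit priming.
    """

    droplets: dict[str, DropletState] = field(default_factory=dict)
    clusters: dict[str, ParticleClusterState] = field(default_factory=dict)
    magnet: MagnetState = field(default_factory=MagnetState)
    sets: dict[str, SurfaceEnergyTrap] = field(default_factory=dict)
    time: float = 0.0
    bounds: Vec = (40.0, 40.0)

    def copy(self) -> "PlatformState":
        return PlatformState(
            droplets={k: replace(d) for k, d in self.droplets.items()},
            clusters={k: replace(c) for k, c in self.clusters.items()},
            magnet=replace(self.magnet),
            sets={k: replace(s) for k, s in self.sets.items()},
            time=self.time,
            bounds=self.bounds,
        )

    def total_droplet_volume(self) -> float:
        return sum(d.volume for d in self.droplets.values())

    def in_bounds(self, point: Vec) -> bool:
        return 0 <= point[0] <= self.bounds[0] and 0 <= point[1] <= self.bounds[1]

    def clamp(self, point: Vec) -> Vec:
        return (min(max(point[0], 0.0), self.bounds[0]), min(max(point[1], 0.0), self.bounds[1]))

    def add_droplet(self, droplet: DropletState) -> None:
        if droplet.id in self.droplets or droplet.id in self.clusters:
            raise ValueError(f"duplicate object id {droplet.id!r}")
        if not self.in_bounds(droplet.center):
            raise ValueError(f"droplet {droplet.id} center {droplet.center} outside bounds {self.bounds}")
        self.droplets[droplet.id] = droplet

    def add_cluster(self, cluster: ParticleClusterState) -> None:
        if cluster.id in self.clusters or cluster.id in self.droplets:
            raise ValueError(f"duplicate object id {cluster.id!r}")
        if cluster.host_droplet_id is not None:
            host = self.droplets.get(cluster.host_droplet_id)
            if host is None:
                raise ValueError(f"cluster {cluster.id} references unknown droplet {cluster.host_droplet_id!r}")
            if not host.contains(cluster.center):
                raise ValueError(f"cluster {cluster.id} center lies outside host droplet {host.id}")
        self.clusters[cluster.id] = cluster

    def add_set(self, trap: SurfaceEnergyTrap) -> None:
        if trap.id in self.sets:
            raise ValueError(f"duplicate SET id {trap.id!r}")
        self.sets[trap.id] = trap
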