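"""Actuation and detection adapters binding the controller to the simulator.

The controller only ever talks to two small contracts:

* **actuation** — ``move_to(point_px, speed)``, ``set_magnet(on)``,
  ``set_power(level)`` (a hardware driver could implement the same contract);
* **detection** — ``capture() -> list[Detection]``.

:class:`SimulatorWorld` implements actuation on the physics simulator and logs
every command, so any run can be replayed on a fresh identical simulator.
:class:`PerfectEyes` derives detections from the exact annotation geometry (a
faithful detector); :class:`DetectorEyes` rasterizes the frame and runs the
classical detector, closing the full image loop.
"""

from __future__ import annotations

from typing import Optional, Protocol

from magloop.imaging.camera import CameraModel
from magloop.imaging.render import AnnotatedFrame, annotate, render
from magloop.sim.engine import anchor_check, contact_merge, step
from magloop.sim.geometry import distance
from magloop.sim.model import EngagementModel
from magloop.sim.state import PlatformState, Vec
from magloop.vision.detector import Detection, DetectorParams, detect


class Actuation(Protocol):
    def move_to(self, point_px: Vec, speed: float) -> None: ...
    def set_magnet(self, on: bool) -> None: ...
    def set_power(self, level: str) -> None: ...
    def settle(self) -> None: ...


class Eyes(Protocol):
    def capture(self) -> list[Detection]: ...


class RecolorRule:
    """Linear RGB interpolation applied to a cluster's host droplet over time."""

    def __init__(self, cluster_id: str, target_color: tuple[int, int, int], duration_s: float):
        if duration_s <= 0:
            raise ValueError("recolor duration must be positive")
        self.cluster_id = cluster_id
        self.target_color = tuple(int(c) for c in target_color)
        self.duration_s = duration_s
        self.elapsed_s = 0.0
        self.start_color: Optional[tuple[int, int, int]] = None

    def apply(self, state: PlatformState, dt: float) -> None:
        cluster = state.clusters.get(self.cluster_id)
        if cluster is None or cluster.host_droplet_id is None:
            return
        droplet = state.droplets.get(cluster.host_droplet_id)
        if droplet is None or droplet.color is None:
            return
        if self.start_color is None:
            self.start_color = droplet.color
        self.elapsed_s = min(self.elapsed_s + dt, self.duration_s)
        f = self.elapsed_s / self.duration_s
        droplet.color = tuple(
            int(round(s + f * (t - s))) for s, t in zip(self.start_color, self.target_color)
        )


class SimulatorWorld:
    """Simulator-backed actuation with command logging and a simulated clock."""

    def __init__(
        self,
        state: PlatformState,
        model: Optional[EngagementModel] = None,
        camera: Optional[CameraModel] = None,
        dt: float = 0.05,
        settle_time: float = 0.5,
    ):
        self.state = state
        self.model = model or EngagementModel()
        self.camera = camera or CameraModel.for_field(*state.bounds)
        self.dt = dt
        self.settle_time = settle_time
        self.log: list[tuple] = []
        self.recolor_rules: list[RecolorRule] = []

    # -- actuation contract -------------------------------------------------
    def move_to(self, point_px: Vec, speed: float) -> None:
        if speed <= 0:
            raise ValueError(f"move_to requires speed > 0, got {speed}")
        target = self.state.clamp(self.camera.to_mm(point_px))
        self.log.append(("move_to", (round(point_px[0], 4), round(point_px[1], 4)), round(speed, 6)))
        guard = 0
        while distance(self.state.magnet.cp, target) > 1e-9:
            self._advance(target, speed)
            guard += 1
            if guard > 200_000:
                raise RuntimeError(f"move_to({target}) did not converge")

    def set_magnet(self, on: bool) -> None:
        self.log.append(("magnet", bool(on)))
        self.state.magnet.engaged = bool(on)

    def set_power(self, level: str) -> None:
        self.log.append(("power", level))
        self.state.magnet.power_level = level

    def settle(self) -> None:
        """Let the hardware catch up with the control point (no CP motion)."""
        self.log.append(("settle",))
        target = self.state.magnet.cp
        for _ in range(max(int(round(self.settle_time / self.dt)), 1)):
            self._advance(target, 0.0)

    # -- clock --------------------------------------------------------------
    def incubate(self, seconds: float, chunk_s: float = 10.0) -> None:
        """Advance the simulated clock with no motion, applying reaction rules."""
        if seconds < 0:
            raise ValueError("incubation must be non-negative")
        self.log.append(("incubate", round(seconds, 3)))
        remaining = seconds
        while remaining > 1e-9:
            dt = min(chunk_s, remaining)
            self.state.time += dt
            for rule in self.recolor_rules:
                rule.apply(self.state, dt)
            remaining -= dt

    def add_recolor(self, cluster_id: str, target_color: tuple[int, int, int], duration_s: float) -> None:
        self.recolor_rules.append(RecolorRule(cluster_id, target_color, duration_s))

    # -- observation helpers ------------------------------------------------
    def render_frame(self, frame_id: str = "capture") -> AnnotatedFrame:
        return render(self.state, self.camera, frame_id=frame_id)

    @property
    def time(self) -> float:
        return self.state.time

    def _advance(self, target_mm: Vec, speed: float) -> None:
        self.state = step(self.state, target_mm, speed, self.dt, self.model)
        self.state = contact_merge(self.state)
        self.state = anchor_check(self.state)


class PerfectEyes:
    """Faithful detector: exact geometric boxes at confidence 1.0."""

    def __init__(self, world: SimulatorWorld):
        self.world = world

    def capture(self) -> list[Detection]:
        annotations = annotate(self.world.state, self.world.camera)
        return [Detection(a.class_label, a.box, 1.0) for a in annotations]


class DetectorEyes:
    """Image-loop detector: rasterize the state and run the classical detector."""

    def __init__(self, world: SimulatorWorld, params: Optional[DetectorParams] = None):
        self.world = world
        self.params = params or DetectorParams()

    def capture(self) -> list[Detection]:
        return detect(self.world.render_frame().image, self.params)


def replay(
    log: list[tuple],
    initial_state: PlatformState,
    model: Optional[EngagementModel] = None,
    camera: Optional[CameraModel] = None,
    dt: float = 0.05,
    settle_time: float = 0.5,
) -> SimulatorWorld:
    """Re-execute a logged command sequence against a fresh simulator."""
    world = SimulatorWorld(initial_state.copy(), model=model, camera=camera, dt=dt, settle_time=settle_time)
    for entry in log:
        kind = entry[0]
        if kind == "move_to":
            world.move_to(entry[1], entry[2])
        elif kind == "magnet":
            world.set_magnet(entry[1])
        elif kind == "power":
            world.set_power(entry[1])
        elif kind == "settle":
            world.settle()
        elif kind == "incubate":
            world.incubate(entry[1])
        else:
            raise ValueError(f"unknown log entry {entry!r}")
    return world
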