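"""End-to-end assay choreographies on the simulated platform.

The choreography layer drives the platform exclusively through the
control-module operations (transport / merge / mix / extract) plus the world's
clock; it never reaches into simulator state.  Chemistry is reduced to a
recolor rule registered on the world at priming time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from magloop.assays.colorimetry import (
    NEGATIVE,
    ColorClassifierConfig,
    classify_color,
    read_droplet_color,
)
from magloop.assays.protocols import (
    HOME_MM,
    HYDROLYZED_YELLOW,
    AssayProtocol,
    StrainProfile,
    build_platform,
)
from magloop.control.adapters import Eyes, PerfectEyes, SimulatorWorld
from magloop.control.config import OperationConfig
from magloop.control.operations import (
    STATUS_SUCCESS,
    OperationResult,
    extract,
    merge,
    mix,
    transport,
)
from magloop.imaging.camera import CameraModel
from magloop.imaging.render import CLASS_DROPLET
from magloop.sim.model import EngagementModel


@dataclass
class AreaReport:
    area_id: str
    operations: dict[str, OperationResult] = field(default_factory=dict)
    incubation_start: Optional[float] = None
    incubation_end: Optional[float] = None
    readout_rgb: Optional[tuple[float, float, float]] = None
    classification: Optional[str] = None

    @property
    def ok(self) -> bool:
        return bool(self.operations) and all(r.ok for r in self.operations.values())


@dataclass
class AssayReport:
    assay: str
    areas: list[AreaReport]
    valid: Optional[bool] = None  # Carba NP control-reaction validity

    @property
    def ok(self) -> bool:
        return all(a.ok for a in self.areas)


def make_world(
    protocol: AssayProtocol,
    model: Optional[EngagementModel] = None,
    camera: Optional[CameraModel] = None,
    dt: float = 0.05,
) -> tuple[SimulatorWorld, PerfectEyes]:
    """Prime a platform for the protocol and wrap it in a world + faithful eyes."""
    state = build_platform(protocol)
    world = SimulatorWorld(state, model=model, camera=camera, dt=dt)
    return world, PerfectEyes(world)


def _home(world: SimulatorWorld, config: OperationConfig) -> None:
    world.set_magnet(False)
    world.move_to(world.camera.to_px(HOME_MM), config.default_speed)


def _merge_and_mix(
    protocol: AssayProtocol, area, world: SimulatorWorld, eyes: Eyes, config: OperationConfig, report: AreaReport
) -> bool:
    px = world.camera.to_px
    report.operations["merge"] = merge(
        config, world, eyes, moving_hint=px(area.reagent_center), still_hint=px(area.sample_center)
    )
    if not report.operations["merge"].ok:
        return False
    report.operations["mix"] = mix(
        protocol.mix_loops, protocol.mix_arm_px, config, world, eyes, particle_hint=px(area.sample_center)
    )
    return report.operations["mix"].ok


def _extract_at_set(area, world: SimulatorWorld, eyes: Eyes, config: OperationConfig, report: AreaReport) -> bool:
    px = world.camera.to_px
    report.operations["to_set"] = transport(
        [px(area.set_center)], config, world, eyes, particle_hint=px(area.sample_center)
    )
    if not report.operations["to_set"].ok:
        return False
    report.operations["extract"] = extract(
        area.extract_direction, area.extract_travel_px, config, world, eyes, particle_hint=px(area.set_center)
    )
    return report.operations["extract"].ok


def _read_area_color(area, world: SimulatorWorld, eyes: Eyes) -> Optional[tuple[float, float, float]]:
    frame = world.render_frame()
    px = world.camera.to_px(area.set_center)
    droplets = [d for d in eyes.capture() if d.class_label == CLASS_DROPLET]
    if not droplets:
        return None
    box = min(droplets, key=lambda d: (d.box.center[0] - px[0]) ** 2 + (d.box.center[1] - px[1]) ** 2).box
    return read_droplet_color(frame.image, box)


def _run_choreography(
    protocol: AssayProtocol,
    world: SimulatorWorld,
    eyes: Eyes,
    config: OperationConfig,
) -> AssayReport:
    """Shared merge→mix→incubate→extract scaffold for both assays."""
    world.set_power(protocol.power_level)
    report = AssayReport(assay=protocol.name, areas=[AreaReport(a.area_id) for a in protocol.areas])

    # merges and mixes run back-to-back; each area's incubation clock starts
    # as soon as its mixing completes, so later areas overlap earlier waits
    for area, area_report in zip(protocol.areas, report.areas):
        try:
            done = _merge_and_mix(protocol, area, world, eyes, config, area_report)
        except Exception as exc:  # precondition/detector failures mark the area, not the assay
            area_report.operations.setdefault("merge", OperationResult("aborted", 0, [], str(exc)))
            done = False
        if done:
            area_report.incubation_start = world.time

    # magnet parks at HOME, switched off, while the reactions incubate
    _home(world, config)

    for area, area_report in zip(protocol.areas, report.areas):
        if area_report.incubation_start is None:
            continue
        remaining = area_report.incubation_start + protocol.incubation_s - world.time
        if remaining > 0:
            world.incubate(remaining)
        area_report.incubation_end = world.time
        try:
            _extract_at_set(area, world, eyes, config, area_report)
        except Exception as exc:
            area_report.operations.setdefault("extract", OperationResult("aborted", 0, [], str(exc)))
        _home(world, config)
    return report


def run_bca(
    protocol: AssayProtocol,
    world: SimulatorWorld,
    eyes: Eyes,
    config: Optional[OperationConfig] = None,
) -> AssayReport:
    """Triplicate protein-quantification choreography.

    The contract ends at successful particle extraction and droplet retrieval;
    the absorbance read is a wet-lab measurement and is not simulated, so the
    readout records the droplet color without classifying it.
    """
    if protocol.name != "BCA":
        raise ValueError(f"expected a BCA protocol, got {protocol.name!r}")
    config = config or OperationConfig()
    report = _run_choreography(protocol, world, eyes, config)
    for area, area_report in zip(protocol.areas, report.areas):
        if area_report.ok:
            area_report.readout_rgb = _read_area_color(area, world, eyes)
    return report


def run_carba_np(
    protocol: AssayProtocol,
    strain_profile: StrainProfile,
    world: SimulatorWorld,
    eyes: Eyes,
    config: Optional[OperationConfig] = None,
    classifier: ColorClassifierConfig = ColorClassifierConfig(),
) -> AssayReport:
    """Paired test/control resistance-detection choreography with color readout.

    A carbapenemase-producing strain hydrolyzes the imipenem in the test
    reaction during incubation, turning it from red toward yellow; the control
    reaction (no imipenem) must stay red for the assay to be valid.
    """
    if protocol.name != "CarbaNP":
        raise ValueError(f"expected a CarbaNP protocol, got {protocol.name!r}")
    config = config or OperationConfig()
    if strain_profile.cpe:
        world.add_recolor("test_particles", HYDROLYZED_YELLOW, protocol.incubation_s)

    report = _run_choreography(protocol, world, eyes, config)
    for area, area_report in zip(protocol.areas, report.areas):
        if not area_report.ok:
            continue  # classification only after every operation succeeded
        area_report.readout_rgb = _read_area_color(area, world, eyes)
        if area_report.readout_rgb is not None:
            area_report.classification = classify_color(area_report.readout_rgb, classifier)

    control = next((a for a in report.areas if a.area_id == "control"), None)
    report.valid = control is not None and control.classification == NEGATIVE
    return report
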