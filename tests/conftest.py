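from __future__ import annotations

import pytest

from magloop.control.adapters import PerfectEyes, SimulatorWorld
from magloop.control.config import OperationConfig
from magloop.imaging.camera import CameraModel
from magloop.sim.model import EngagementModel
from magloop.sim.state import (
    DropletState,
    ParticleClusterState,
    PlatformState,
    SurfaceEnergyTrap,
)


@pytest.fixture
def model() -> EngagementModel:
    return EngagementModel()


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture
def config() -> OperationConfig:
    return OperationConfig()


def build_state(
    droplet_volume: float = 10.0,
    particle_volume: float = 0.5,
    center=(10.0, 20.0),
    sets=(),
    extra_droplets=(),
) -> PlatformState:
    """One particle-bearing droplet plus optional SETs / extra droplets."""
    state = PlatformState()
    for trap_id, trap_center, radius in sets:
        state.add_set(SurfaceEnergyTrap(id=trap_id, center=trap_center, radius=radius))
    droplet = DropletState(
        id="d1", center=center, volume=droplet_volume, particle_volume_inside=particle_volume
    )
    state.add_droplet(droplet)
    if particle_volume > 0:
        state.add_cluster(
            ParticleClusterState(id="p1", center=center, volume=particle_volume, host_droplet_id="d1")
        )
    for spec in extra_droplets:
        state.add_droplet(DropletState(**spec))
    return state


def make_world(state: PlatformState, model: EngagementModel | None = None):
    world = SimulatorWorld(state, model=model)
    return world, PerfectEyes(world)


@pytest.fixture
def transport_world(model):
    return make_world(build_state(), model)
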