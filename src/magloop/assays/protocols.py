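"""Assay protocol definitions and platform priming.

Two demonstrated choreographies:

* **BCA** protein quantification — three reaction areas, each primed with a
  20-μl working-reagent droplet carrying 1.5 μl of particles and a 2-μl
  protein droplet, one SET per area, run at high magnet power; merge, 5 mixing
  loops, 10-min incubation, SET-assisted particle extraction.
* **Carba NP** resistance detection — two reaction pairs (test with imipenem,
  control without), each a 10-μl solution-A droplet with 1.5 μl of particles
  plus a 10-μl lysate droplet and a SET; merge, mix, 1-h incubation during
  which a CPE strain turns the test reaction from red toward yellow, then
  extraction and colorimetric readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from magloop.sim.model import POWER_DEFAULT, POWER_HIGH
from magloop.sim.state import DropletState, ParticleClusterState, PlatformState, SurfaceEnergyTrap

SOLUTION_A_RED = (200, 45, 50)
HYDROLYZED_YELLOW = (235, 190, 45)
BCA_REAGENT_GREEN = (110, 190, 130)

#: HOME position of the electromagnet, mm (near the field's top-left corner).
HOME_MM = (2.0, 2.0)


@dataclass(frozen=True)
class AreaLayout:
    """One reaction area: reagent + sample droplets and a surface energy trap."""

    area_id: str
    reagent_center: tuple[float, float]  # mm
    reagent_volume: float  # μl
    particle_volume: float  # μl, inside the reagent droplet
    sample_center: tuple[float, float]
    sample_volume: float
    set_center: tuple[float, float]
    set_radius: float = 1.5
    reagent_color: Optional[tuple[int, int, int]] = None
    extract_direction: str = "EAST"
    extract_travel_px: float = 60.0


@dataclass(frozen=True)
class AssayProtocol:
    name: str  # "BCA" | "CarbaNP"
    areas: tuple[AreaLayout, ...]
    power_level: str
    mix_loops: int
    mix_arm_px: float
    incubation_s: float

    def __post_init__(self) -> None:
        if self.name not in ("BCA", "CarbaNP"):
            raise ValueError(f"unknown assay {self.name!r}")
        if self.mix_loops < 1 or self.incubation_s <= 0:
            raise ValueError("mix_loops must be >= 1 and incubation_s > 0")


def bca_protocol() -> AssayProtocol:
    areas = tuple(
        AreaLayout(
            area_id=f"area{i + 1}",
            reagent_center=(10.0, y),
            reagent_volume=20.0,
            particle_volume=1.5,
            sample_center=(16.0, y),
            sample_volume=2.0,
            set_center=(30.0, y),
            reagent_color=BCA_REAGENT_GREEN,
        )
        for i, y in enumerate((8.0, 20.0, 32.0))
    )
    return AssayProtocol(
        name="BCA", areas=areas, power_level=POWER_HIGH, mix_loops=5, mix_arm_px=25.0, incubation_s=600.0
    )


def carba_np_protocol() -> AssayProtocol:
    areas = (
        AreaLayout(
            area_id="control",
            reagent_center=(8.0, 12.0),
            reagent_volume=10.0,
            particle_volume=1.5,
            sample_center=(8.0, 24.0),
            sample_volume=10.0,
            set_center=(8.0, 36.0),
            reagent_color=SOLUTION_A_RED,
        ),
        AreaLayout(
            area_id="test",
            reagent_center=(28.0, 12.0),
            reagent_volume=10.0,
            particle_volume=1.5,
            sample_center=(28.0, 24.0),
            sample_volume=10.0,
            set_center=(28.0, 36.0),
            reagent_color=SOLUTION_A_RED,
        ),
    )
    return AssayProtocol(
        name="CarbaNP", areas=areas, power_level=POWER_DEFAULT, mix_loops=3, mix_arm_px=25.0, incubation_s=3600.0
    )


def build_platform(protocol: AssayProtocol) -> PlatformState:
    """Prime a fresh platform with the protocol's droplets, particles and SETs."""
    state = PlatformState()
    for area in protocol.areas:
        reagent = DropletState(
            id=f"{area.area_id}_reagent",
            center=area.reagent_center,
            volume=area.reagent_volume,
            particle_volume_inside=area.particle_volume,
            color=area.reagent_color,
        )
        state.add_droplet(reagent)
        state.add_cluster(
            ParticleClusterState(
                id=f"{area.area_id}_particles",
                center=area.reagent_center,
                volume=area.particle_volume,
                host_droplet_id=reagent.id,
            )
        )
        state.add_droplet(
            DropletState(id=f"{area.area_id}_sample", center=area.sample_center, volume=area.sample_volume)
        )
        state.add_set(SurfaceEnergyTrap(id=f"{area.area_id}_set", center=area.set_center, radius=area.set_radius))
    return state


@dataclass(frozen=True)
class StrainProfile:
    sample_id: str
    beta_lactamase: str
    species: str
    cpe: bool


#: The eight-strain panel: six carbapenemase producers, two non-producers.
STRAIN_TABLE: tuple[StrainProfile, ...] = (
    StrainProfile("2", "IMP", "Escherichia coli NCTC 13476", True),
    StrainProfile("7", "KPC", "E. coli 6013499989", True),
    StrainProfile("8", "KPC", "Klebsiella pneumoniae 6033440078", True),
    StrainProfile("9", "IMP", "Serratia marcescens 6013550755", True),
    StrainProfile("11", "NDM", "K. pneumoniae 2073318014", True),
    StrainProfile("14", "NDM", "E. coli MBRL 235", True),
    StrainProfile("26", "None", "K. pneumoniae C13 (6123-145679)", False),
    StrainProfile("27", "None", "E. coli C18 (7013-614848)", False),
)
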