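"""Parametric engagement model: speed thresholds of the three interaction regimes.

The thresholds are linear in the particle quantity:

* ``disengagement_speed`` — maximum speed at which the magnet still couples to
  the cluster; above it the magnet outruns the particles.
* ``extraction_speed`` — minimum speed needed to pull the cluster across the
  droplet boundary against surface-tension retention; anchoring the droplet on
  a surface energy trap lowers it by ``set_factor``.

An unanchored droplet can additionally keep up with its cluster below the
droplet-drag baseline ``k_drag``, so phase separation from a free droplet only
happens at speeds >= max(extraction_speed, k_drag).  The constraint
``k_mag > k_exit`` keeps the extraction-feasible window non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass

POWER_DEFAULT = "default"  # 24 V / 0.8 A
POWER_HIGH = "high"  # 36 V / 1.2 A
POWER_LEVELS = (POWER_DEFAULT, POWER_HIGH)


@dataclass(frozen=True)
class EngagementModel:
    """Coupling constants of the magnet/particle/droplet interaction.

    Attributes
    ----------
    k_mag:
        Magnet–particle coupling, mm/(s·μl).
    k_exit:
        Surface-tension retention, mm/(s·μl).
    k_drag:
        Droplet drag baseline, mm/s: below this speed a free droplet follows
        its cluster regardless of the retention threshold.
    set_factor:
        Multiplier in (0, 1) applied to the extraction threshold when the
        droplet is anchored on a surface energy trap.
    power_gain:
        Threshold multiplier (>= 1) at the high power level.
    residual_fraction:
        Fraction of the cluster volume left behind in the droplet after a
        successful extraction (too small to be detected downstream).
    recenter_tau:
        Time constant (s) of capillary recentering: a dragged droplet relaxes
        onto its particle pile, so offsets (e.g. right after a merge) decay.
    """

    k_mag: float = 20.0
    k_exit: float = 8.0
    k_drag: float = 12.0
    set_factor: float = 0.5
    power_gain: float = 1.5
    residual_fraction: float = 0.02
    recenter_tau: float = 0.3

    def __post_init__(self) -> None:
        if not self.k_mag > self.k_exit > 0:
            raise ValueError(f"require k_mag > k_exit > 0, got k_mag={self.k_mag}, k_exit={self.k_exit}")
        if not 0 < self.set_factor < 1:
            raise ValueError(f"set_factor must be in (0, 1), got {self.set_factor}")
        if self.power_gain < 1:
            raise ValueError(f"power_gain must be >= 1, got {self.power_gain}")
        if self.k_drag < 0:
            raise ValueError(f"k_drag must be non-negative, got {self.k_drag}")
        if not 0 <= self.residual_fraction < 1:
            raise ValueError(f"residual_fraction must be in [0, 1), got {self.residual_fraction}")
        if self.recenter_tau <= 0:
            raise ValueError(f"recenter_tau must be > 0, got {self.recenter_tau}")

    def gain(self, power_level: str) -> float:
        if power_level not in POWER_LEVELS:
            raise ValueError(f"unknown power level {power_level!r}; expected one of {POWER_LEVELS}")
        return self.power_gain if power_level == POWER_HIGH else 1.0


def disengagement_speed(model: EngagementModel, particle_volume: float, power_level: str = POWER_DEFAULT) -> float:
    """Maximum drag speed (mm/s) before the magnet loses the cluster."""
    if particle_volume < 0:
        raise ValueError(f"particle_volume must be >= 0, got {particle_volume}")
    return model.k_mag * particle_volume * model.gain(power_level)


def extraction_speed(
    model: EngagementModel,
    particle_volume: float,
    anchored: bool = False,
    power_level: str = POWER_DEFAULT,
) -> float:
    """Minimum speed (mm/s) to pull the cluster out of its droplet."""
    if particle_volume <= 0:
        raise ValueError(f"particle_volume must be > 0, got {particle_volume}")
    v = model.k_exit * particle_volume / model.gain(power_level)
    if anchored:
        v *= model.set_factor
    return v


def release_speed(
    model: EngagementModel,
    particle_volume: float,
    anchored: bool,
    power_level: str = POWER_DEFAULT,
) -> float:
    """Effective threshold at which the cluster separates from its droplet.

    Anchored droplets are pinned, so bare ``extraction_speed`` applies; a free
    droplet also has to be outrun, hence the ``k_drag`` floor.
    """
    v = extraction_speed(model, particle_volume, anchored=anchored, power_level=power_level)
    return v if anchored else max(v, model.k_drag)
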