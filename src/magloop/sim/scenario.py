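"""Scenario configuration files and state traces.

A scenario is a human-editable YAML document declaring droplets, particle
clusters, surface energy traps, engagement-model constants and magnet
defaults::

    bounds: [40, 40]
    model: {k_mag: 20, k_exit: 8, k_drag: 12, set_factor: 0.5, power_gain: 1.5}
    magnet: {position: [2, 2], power: default, lag: 0}
    droplets:
      - {id: d1, center: [10, 20], volume: 10, particle_volume: 0.5}
      - {id: d2, center: [25, 20], volume: 10, color: [200, 45, 50]}
    clusters:
      - {id: free1, center: [35, 5], volume: 0.5}
    sets:
      - {id: s1, center: [30, 20], radius: 1.5}

A droplet with ``particle_volume > 0`` implicitly spawns a hosted cluster
``<id>_p`` at its center.  Traces are line-delimited JSON records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import yaml

from magloop.sim.model import EngagementModel
from magloop.sim.state import (
    DropletState,
    MagnetState,
    ParticleClusterState,
    PlatformState,
    SurfaceEnergyTrap,
)


class ScenarioError(ValueError):
    """Raised for malformed scenario configuration."""


def build_scenario(config: dict) -> tuple[PlatformState, EngagementModel]:
    """Build a platform state and engagement model from a parsed config dict."""
    try:
        bounds = tuple(float(v) for v in config.get("bounds", (40.0, 40.0)))
        model = EngagementModel(**config.get("model", {}))
        magnet_cfg = dict(config.get("magnet", {}))
        if "position" in magnet_cfg:
            magnet_cfg["position"] = tuple(float(v) for v in magnet_cfg["position"])
        if "power" in magnet_cfg:
            magnet_cfg["power_level"] = magnet_cfg.pop("power")
        magnet = MagnetState(**magnet_cfg)
    except (TypeError, ValueError) as exc:
        raise ScenarioError(str(exc)) from exc

    state = PlatformState(magnet=magnet, bounds=bounds)  # type: ignore[arg-type]
    for spec in config.get("sets", []):
        state.add_set(SurfaceEnergyTrap(id=str(spec["id"]), center=tuple(spec["center"]), radius=float(spec["radius"])))
    for spec in config.get("droplets", []):
        particle_volume = float(spec.get("particle_volume", 0.0))
        droplet = DropletState(
            id=str(spec["id"]),
            center=tuple(float(v) for v in spec["center"]),
            volume=float(spec["volume"]),
            particle_volume_inside=particle_volume,
            color=tuple(spec["color"]) if spec.get("color") else None,
        )
        state.add_droplet(droplet)
        if particle_volume > 0:
            state.add_cluster(
                ParticleClusterState(
                    id=f"{droplet.id}_p",
                    center=droplet.center,
                    volume=particle_volume,
                    host_droplet_id=droplet.id,
                )
            )
    for spec in config.get("clusters", []):
        state.add_cluster(
            ParticleClusterState(
                id=str(spec["id"]),
                center=tuple(float(v) for v in spec["center"]),
                volume=float(spec["volume"]),
                host_droplet_id=spec.get("host"),
            )
        )
    return state, model


def load_scenario(path: Union[str, Path]) -> tuple[PlatformState, EngagementModel]:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ScenarioError(f"scenario file {path} does not contain a mapping")
    return build_scenario(config)


def state_records(state: PlatformState) -> list[dict]:
    """Flatten a state into per-object trace records."""
    records = []
    for droplet in state.droplets.values():
        records.append(
            {
                "time": round(state.time, 6),
                "id": droplet.id,
                "class": "droplet",
                "center": [round(droplet.center[0], 4), round(droplet.center[1], 4)],
                "volume": round(droplet.volume, 6),
                "anchored": droplet.anchored_set_id,
            }
        )
    for cluster in state.clusters.values():
        records.append(
            {
                "time": round(state.time, 6),
                "id": cluster.id,
                "class": "particle",
                "center": [round(cluster.center[0], 4), round(cluster.center[1], 4)],
                "volume": round(cluster.volume, 6),
                "host": cluster.host_droplet_id,
            }
        )
    return records


def save_trace(states: Iterable[PlatformState], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for state in states:
            for record in state_records(state):
                fh.write(json.dumps(record, sort_keys=True) + "\n")
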