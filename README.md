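# magloop

Closed-loop, image-feedback droplet control for magnetic digital microfluidics
(MDM), fully simulated and hardware-free. A magnet drags particle clusters to
transport, merge, mix and phase-separate microliter droplets on an open
substrate; a detector watches the scene, and a feedback controller judges each
operation against pixel-space success criteria and rectifies failures by
retrying at an adjusted speed — lower when the magnet disengages during
transport, higher when particle extraction fails.

## Modules

| module | what it does |
| --- | --- |
| `magloop.sim` | Deterministic physics-lite simulator: droplets, particle clusters, magnet (with optional actuator lag), surface energy traps (SETs); the three interaction regimes (transport / disengagement / extraction) via a linear threshold model; contact merging; SET anchoring; YAML scenarios and JSONL traces. |
| `magloop.imaging` | Renders platform states into camera-like frames (25–1000 lux) with exact ground-truth bounding boxes, and generates synthetic datasets across six scene categories (P/D ratios, aspect ratios, boundary motion, illumination, two colored-reagent looks). |
| `magloop.vision` | Classical droplet/particle detector (pluggable: anything `image -> list[Detection]`), IoU, greedy nearest-centroid tracking, COCO-style evaluation (101-point AP, mAP over IoU 0.50:0.05:0.95), deterministic dataset splitting, COCO JSON + detections-JSONL I/O. |
| `magloop.control` | The four closed-loop operations (`transport`, `extract`, `merge`, `mix`) as retrying state machines that act only on detector output; success criteria (10 px destination tolerance, box disjointness, ≥3 px growth in both dimensions); actuation/detection interface contracts; command logging and replay. |
| `magloop.assays` | Choreographies for BCA protein quantification (triplicate: merge, 5 mixing loops, 10-min incubation, SET-assisted extraction) and the Carba NP resistance test (paired test/control reactions, 1-h incubation, red vs yellow/orange hue readout with control-validity rule), plus the eight-strain reference panel. |
| `magloop.interface` | The `magloop` CLI. |

## CLI

```bash
# closed-loop operations against a scenario
magloop simulate examples/scenario_transport.yaml examples/script_demo.yaml --out-dir run/

# synthetic annotated dataset + 70/30 split (COCO JSON + PNG frames)
magloop generate --frames 769 --seed 1 --out-dir dataset/

# score a detections file against COCO ground truth
magloop evaluate --detections dets.jsonl --truth dataset/annotations.json --out report.json

# full assay choreographies
magloop assay bca --out bca.json
magloop assay carba-np --strain 2 --out carba.json
```

Exit codes: 0 success, 1 operation failure (retries exhausted), 2
configuration error.

## Notes

- Everything is deterministic: the simulator has no randomness, and one seed
  drives all dataset generation; identical config + seed yields byte-identical
  logs and frames.
- The controller sees only `Detection` objects — swap `PerfectEyes` (exact
  geometry) for `DetectorEyes` (rendered frame + classical detector) or any
  object with a `capture()` method.
- Neural-network training/inference is out of scope; the classical detector
  stands in behind the same interface.
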