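"""Frame-to-frame association of detections by greedy nearest-centroid matching."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from magloop.vision.detector import Detection


@dataclass
class AssociationResult:
    matches: dict[int, int]  # previous index -> current index
    new: list[int]  # current indices with no previous match
    lost: list[int]  # previous indices with no current match


def associate(previous: Sequence[Detection], current: Sequence[Detection], gate: float) -> AssociationResult:
    """Match detections across frames within class, no match beyond ``gate`` px.

    Candidate pairs are sorted by (distance, previous index, current index) and
    taken greedily, so between equidistant candidates the lower index wins.
    """
    if gate <= 0:
        raise ValueError(f"gate must be > 0, got {gate}")
    pairs = []
    for i, p in enumerate(previous):
        for j, c in enumerate(current):
            if p.class_label != c.class_label:
                continue
            d = math.dist(p.box.center, c.box.center)
            if d <= gate:
                pairs.append((d, i, j))
    pairs.sort()
    matches: dict[int, int] = {}
    used_current: set[int] = set()
    for _, i, j in pairs:
        if i in matches or j in used_current:
            continue
        matches[i] = j
        used_current.add(j)
    new = [j for j in range(len(current)) if j not in used_current]
    lost = [i for i in range(len(previous)) if i not in matches]
    return AssociationResult(matches=matches, new=new, lost=lost)
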