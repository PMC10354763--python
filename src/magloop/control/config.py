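"""Operation parameters.

The pixel thresholds and default speed are the platform's documented success
criteria; the retry factors and cap are configuration (geometric schedules
guarantee the feasibility threshold is crossed).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OperationConfig:
    destination_tolerance: float = 10.0  # px, inclusive
    overshoot: float = 20.0  # px, applied along +y then reversed
    merge_growth: float = 3.0  # px, required in BOTH box dimensions
    default_speed: float = 8.33  # mm/s
    retry_slowdown: float = 0.6  # transport retries: speed multiplier < 1
    retry_speedup: float = 1.5  # extraction retries: speed multiplier > 1
    max_retries: int = 5

    def __post_init__(self) -> None:
        if min(self.destination_tolerance, self.overshoot, self.merge_growth, self.default_speed) <= 0:
            raise ValueError("all pixel/speed parameters must be positive")
        if not 0 < self.retry_slowdown < 1:
            raise ValueError(f"retry_slowdown must be in (0, 1), got {self.retry_slowdown}")
        if self.retry_speedup <= 1:
            raise ValueError(f"retry_speedup must be > 1, got {self.retry_speedup}")
        if self.max_retries < 0:
            raise ValueError(f"max_retries must be >= 0, got {self.max_retries}")
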