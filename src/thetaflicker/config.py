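"""Analysis configuration: every tunable of the pipeline in one record.

The configuration is serialised (YAML/JSON) alongside results and hashed,
so every output table is traceable to the exact parameter set that
produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # arena / binning
    arena_side_cm: float = 60.0
    bin_cm: float = 3.0
    # behaviour
    speed_min_cms: float = 2.0
    velocity_smooth_ms: float = 200.0
    # ratemaps / templates
    occupancy_floor_s: float = 0.2
    coverage_min: float = 0.9
    remap_r_threshold: float = 0.5
    # theta
    theta_low_hz: float = 6.0
    theta_high_hz: float = 11.0
    n_phase_bins: int = 36
    cycle_min_s: float = 1.0 / 12.0
    cycle_max_s: float = 0.2
    # classification
    min_specific_cells: int = 2
    mpv_min_per_side: int = 2
    incidence_mode: str = "pooled"
    thirds_mode: str = "equal"
    # decoding
    bayes_rate_floor_hz: float = 0.01
    bayes_threshold: float = 0.95
    periphery_frac: float = 0.1
    # statistics
    n_interval_sim: int = 5000
    n_shuffle: int = 1000
    autocorr_max_lag: int = 20
    downsample_min_s: float = 5.0
    downsample_min_cm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta_low_hz < self.theta_high_hz):
            raise ValueError("invalid theta band")
        if not (0 < self.bayes_threshold < 1):
            raise ValueError("bayes_threshold must be in (0, 1)")
        if self.min_specific_cells < 1 or self.mpv_min_per_side < 1:
            raise ValueError("cell minima must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        return cls(**yaml.safe_load(text))

    @property
    def hash(self) -> str:
        """Short stable digest of the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
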