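"""Analysis configuration: the defect-calling thresholds and pipeline knobs.

The defaults encode the calling rules used throughout the package: a cell
cycle is deviant only when it is both beyond ``cycle_sd_mult`` standard
deviations and at least ``cycle_min_delta`` minutes from the wild-type
mean, and a position is deviant only when the deviation from the expected
position and the neighbor-distance score both exceed ``pos_sd_mult``
standard deviations of their wild-type baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    cycle_sd_mult: float = 3.0        # SD multiplier for cycle-length defects
    cycle_min_delta: float = 5.0      # minutes; absolute floor for cycle defects
    pos_sd_mult: float = 3.5          # SD multiplier for position + neighbor defects
    n_neighbors: int = 10             # wild-type nearest neighbors in the score
    min_neighbors: int = 5            # fewer surviving neighbors -> score undefined
    n_bootstrap: int = 100_000        # sister-pair bootstrap iterations
    rng_seed: int = 0
    endpoint_stage: str = "comma stage, ~400 min"
    endpoint_min: float = 400.0       # analysis endpoint on the reference clock
    sampling_min: float = 1.5         # imaging cadence, minutes
    cycle_sd_floor: float = 0.5       # minutes; see reference-model docs
    pos_sd_floor: float = 0.3         # µm
    allow_scale: bool = False         # uniform scale in spatial alignment
    xy_um_per_px: float = 0.09        # nuclei-file pixel pitch
    z_um_per_plane: float = 0.5       # nuclei-file plane spacing

    def __post_init__(self) -> None:
        if self.cycle_sd_mult <= 0 or self.pos_sd_mult <= 0:
            raise ConfigError("SD multipliers must be positive")
        if self.n_neighbors < 1:
            raise ConfigError("n_neighbors must be >= 1")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.sampling_min <= 0:
            raise ConfigError("sampling_min must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
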