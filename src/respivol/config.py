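"""Pipeline configuration: TOML file with command-line overrides."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Run-wide settings; defaults mirror the study protocol."""

    marker_diameter_mm: float = 13.0
    tiffeneau_threshold: float = 0.80
    axis_direction: str = "x_increasing_caudal"
    baseline_y_px: float | None = None  # user-supplied unless a frames index provides it
    detector_backend: str = "threshold"
    output_dir: str = "."
    rng_seed: int = 0
    fvc_lower_limit: float | None = None

    def __post_init__(self):
        if self.marker_diameter_mm <= 0:
            raise ParameterError("marker_diameter_mm must be positive")
        if self.tiffeneau_threshold <= 0:
            raise ParameterError("tiffeneau_threshold must be positive")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from TOML, then apply non-None keyword overrides (flags win)."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def apply_overrides(self, **overrides) -> "PipelineConfig":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**vals)
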