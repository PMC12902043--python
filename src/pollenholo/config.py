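"""Run configuration: a single YAML document driving the whole pipeline.

Defaults echo the reference acquisition: 658 nm illumination, 2.0 μm
pixels, 200 GS iterations, and an autofocus scan of 2300–2800 μm in 10 μm
steps.  Unknown keys anywhere in the document are rejected rather than
ignored, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .exceptions import InvalidArgumentError

__all__ = ["GeometryConfig", "ReconstructionConfig", "SimulationConfig",
           "StatsConfig", "RunConfig", "load_config"]


def _from_mapping(cls, data: dict, context: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise InvalidArgumentError(
            f"unknown key(s) {sorted(unknown)} in {context} config")
    return cls(**data)


@dataclass
class GeometryConfig:
    n_x: int = 3840
    n_y: int = 2160
    pitch: float = 2.0          # μm
    wavelength: float = 0.658   # μm


@dataclass
class ReconstructionConfig:
    n_iterations: int = 200
    clip_level: float = 1.0
    pad_factor: int = 2
    background_method: str = "frame_mean"
    record_misfit: bool = True
    h: Optional[float] = None   # μm; None → autofocus over the scan below
    h_min: float = 2300.0
    h_max: float = 2800.0
    h_step: float = 10.0
    refine: bool = True


@dataclass
class SimulationConfig:
    n_grains: int = 12
    h: float = 2546.0                    # μm, object-to-sensor distance
    photons_at_unit_intensity: float = 5000.0
    read_noise_sd: float = 2.0
    bit_depth: int = 12
    seed: int = 0


@dataclass
class StatsConfig:
    accuracy_decimals: int = 1
    f1_decimals: int = 3
    kappa_decimals: int = 2


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - {"geometry", "reconstruction", "simulation", "stats"}
        if unknown:
            raise InvalidArgumentError(f"unknown top-level key(s) {sorted(unknown)}")
        return cls(
            geometry=_from_mapping(GeometryConfig, data.get("geometry", {}), "geometry"),
            reconstruction=_from_mapping(ReconstructionConfig,
                                         data.get("reconstruction", {}), "reconstruction"),
            simulation=_from_mapping(SimulationConfig, data.get("simulation", {}),
                                     "simulation"),
            stats=_from_mapping(StatsConfig, data.get("stats", {}), "stats"),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML; missing path → all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise InvalidArgumentError("config document must be a mapping")
    return RunConfig.from_dict(data)
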