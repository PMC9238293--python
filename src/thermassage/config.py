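"""Declarative run configuration.

A single YAML mapping drives a simulation; every device and physiology
constant has a default mirroring the modeled massage bed, so an empty config
reproduces the 45 degC scene. The schema is strict: unknown keys are
rejected with their key path.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import anatomy as _anatomy

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "config_digest",
]


class ConfigError(ValueError):
    """Invalid configuration; message lists offending key paths."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerConfig(_Strict):
    name: str
    thickness_mm: float = Field(gt=0)


class SpineConfig(_Strict):
    enabled: bool = False
    cord_mm: float = Field(default=1.9, gt=0)
    csf_mm: float = Field(default=2.9, gt=0)
    epidural_fat_mm: float = Field(default=2.2, gt=0)
    vertebra_mm: float = Field(default=15.0, gt=0)
    center_x_mm: float = 0.0
    start_depth_mm: float = Field(default=20.0, gt=0)


class AnatomyConfig(_Strict):
    layers: list[LayerConfig] = Field(
        default_factory=lambda: [
            LayerConfig(name=l.name, thickness_mm=l.thickness_mm)
            for l in _anatomy.DEFAULT_LAYERS
        ]
    )
    lateral_extent_mm: float = Field(default=300.0, gt=0)
    vertical_extent_mm: float = Field(default=200.0, gt=0)
    depth_extent_mm: float = Field(default=100.0, gt=0)
    spacing_mm: float = Field(default=1.0, gt=0)
    spine: SpineConfig = SpineConfig()


class ActuatorConfig(_Strict):
    centers_mm: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(c) for c in _anatomy.DEFAULT_ACTUATOR_CENTERS_MM]
    )
    radius_mm: float = Field(default=_anatomy.ACTUATOR_RADIUS_MM, gt=0)
    temperature_C: float = 45.0


class SourcesConfig(_Strict):
    actuators: ActuatorConfig = ActuatorConfig()
    mat_temperature_C: float = 40.0
    mat_half_width_mm: Optional[float] = None  # None: mat covers the surface
    h_W_m2K: float = Field(default=5.0, ge=0)
    ambient_C: float = 25.0
    cut_temperature_C: float = 37.0
    lateral_mode: Literal["dirichlet", "adiabatic"] = "dirichlet"


class SolverConfig(_Strict):
    rtol: float = Field(default=1e-8, gt=0, lt=1)
    maxiter: int = Field(default=20_000, gt=0)
    coarse_init: bool = True  # warm-start fine grids from a 2x-coarser solve


class CirculationConfig(_Strict):
    form: Literal["logistic", "printed_exp", "clamped_exp"] = "logistic"
    fit_baseline_C: float = 34.9  # unheated reference of the leg calibration
    core_temperature_C: float = 37.0  # unheated reference for back predictions
    calibration: str = "builtin"  # or a CSV path (temperature_C, flow_L_min)


class OutputsConfig(_Strict):
    directory: str = "runs"
    formats: list[Literal["csv", "vtk", "npz"]] = Field(
        default_factory=lambda: ["csv", "npz"]
    )


class SimulationConfig(_Strict):
    anatomy: AnatomyConfig = AnatomyConfig()
    sources: SourcesConfig = SourcesConfig()
    solver: SolverConfig = SolverConfig()
    circulation: CirculationConfig = CirculationConfig()
    outputs: OutputsConfig = OutputsConfig()
    sweep_temperatures_C: list[float] = Field(
        default_factory=lambda: [45.0, 50.0, 55.0, 60.0, 65.0]
    )

    @field_validator("sweep_temperatures_C")
    @classmethod
    def _sorted_settings(cls, v: list[float]) -> list[float]:
        return sorted(v)


def default_config() -> SimulationConfig:
    """The packaged defaults: 45 degC actuators over a 40 degC mat at 1 mm."""
    ref = importlib.resources.files("thermassage.data") / "default_config.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_config(path)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML config; raise ConfigError with key paths."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid configuration:\n" + "\n".join(lines)) from None


def config_digest(cfg: SimulationConfig) -> str:
    """Stable digest of the semantic config content."""
    payload = cfg.model_dump_json()
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
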