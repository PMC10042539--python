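"""JSON run configuration: defaults, validation, round-trip save/load."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

from .abm import ABMParams
from .classify import GateParams
from .errors import ConfigError
from .qpi import OpticalConstants

__all__ = [
    "SegmentationParams",
    "TrackingParams",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SegmentationParams:
    min_area: int = 200
    closing_radius: int = 3
    expand_px: int = 3

    def __post_init__(self) -> None:
        if self.min_area < 0 or self.closing_radius < 0 or self.expand_px < 0:
            raise ConfigError("segmentation parameters must be non-negative")


@dataclass(frozen=True)
class TrackingParams:
    max_displacement: float = 20.0  # um per frame
    division_mass_tolerance: float = 0.2
    max_doubling: float = 40.0  # h, cytokinesis cutoff
    min_observation: float = 30.0  # h, censoring cutoff
    min_growth_fit: float = 5.0  # h, shortest track entering class growth means
    max_fit_residual_frac: float = 0.03  # relative RMS residual cutoff for clean fits

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ConfigError("max_displacement must be positive")
        if not 0 < self.division_mass_tolerance < 1:
            raise ConfigError("division_mass_tolerance must be in (0, 1)")
        if self.max_doubling <= 0 or self.min_observation < 0:
            raise ConfigError("time cutoffs must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for the CLI and pipeline.

    All blocks have defaults matching the imaging setup and study design:
    623 nm illumination, alpha = 0.185 um^3/pg, 0.36 um^2 pixels, 15-min
    frames, 40 h doubling time, 1.5x/2x fluorescence gates, 6 um rolling
    ball, transfer fraction f = 0.05 and growth multiplier r = 1.15.
    """

    optical: OpticalConstants = field(default_factory=OpticalConstants)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    gates: GateParams = field(default_factory=GateParams)
    abm: ABMParams = field(default_factory=ABMParams)
    frame_interval: float = 0.25  # h
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log_level {self.log_level!r}")


_BLOCKS = {
    "optical": OpticalConstants,
    "segmentation": SegmentationParams,
    "tracking": TrackingParams,
    "gates": GateParams,
    "abm": ABMParams,
}


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")
    coerced = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in {context}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON config, applying defaults for absent keys.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except FileNotFoundError:
        raise
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")

    top = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            if not isinstance(block, dict):
                raise ConfigError(f"config block {name!r} must be an object")
            kwargs[name] = _build(cls, block, name)
    for name in top - set(_BLOCKS):
        if name in data:
            kwargs[name] = data[name]
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as JSON (full precision; round-trips via load_config)."""
    out = dataclasses.asdict(config)
    Path(path).write_text(json.dumps(out, indent=2, default=list) + "\n")
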