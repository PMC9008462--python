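"""Pipeline configuration: nested dataclass sections, YAML round-trip,
strict (unknown-key-rejecting) validation."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .camera import CameraModel
from .detection import DetectionConfig
from .geometry import ChamberGeometry
from .linking import LinkConfig
from .motion import BlinkModel
from .segmentation import SegmentationConfig

__all__ = ["SimulationSection", "PipelineConfig", "ConfigError",
           "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content (exit code 2 in the CLI)."""


@dataclass(frozen=True)
class SimulationSection:
    preset: str = "distal"
    n_tracks: int = 5
    total_time_s: float = 120.0
    render: bool = False
    photons_per_frame: float = 400.0
    bg_photons_px: float = 5.0
    psf_sigma_px: float = 1.3
    blinking: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkConfig = field(default_factory=LinkConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    blink: BlinkModel = field(default_factory=BlinkModel)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    seed: int = 0


_SECTIONS = {
    "camera": CameraModel,
    "detection": DetectionConfig,
    "linking": LinkConfig,
    "segmentation": SegmentationConfig,
    "geometry": ChamberGeometry,
    "blink": BlinkModel,
    "simulation": SimulationSection,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under '{path}'; "
            f"known keys: {sorted(known)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid section '{path}': {e}") from None


def load_config(source) -> PipelineConfig:
    """Build a config from a YAML file path, YAML string, or dict."""
    if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source
            and len(source) < 4096 and Path(source).exists()):
        data = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        data = yaml.safe_load(source)
    else:
        data = source
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return PipelineConfig(seed=seed, **kwargs)


def dump_config(config: PipelineConfig) -> str:
    """Serialize a config to YAML (all values explicit, for the manifest)."""
    out = {"seed": config.seed}
    for name in _SECTIONS:
        section = getattr(config, name)
        out[name] = {f.name: _plain(getattr(section, f.name))
                     for f in dataclasses.fields(section)}
    return yaml.safe_dump(out, sort_keys=True)


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]
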