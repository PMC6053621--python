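"""YAML run configuration with a frozen schema.

One file configures the whole train/segment/evaluate workflow.  Unknown
keys are rejected (typos should fail loudly, not silently fall back to
defaults), every field has a documented default, and a written effective
config reloads to an identical run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .features import FeatureConfig
from .model import TrainConfig
from .pipeline import PipelineConfig
from .superpixel import SlicConfig
from .synthetic_data import SceneConfig

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "load_config", "save_config", "SCHEMA_VERSION"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a run, grouped per pipeline stage."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    n_scenes: int = 5
    scene: SceneConfig = field(default_factory=SceneConfig)
    slic: SlicConfig = field(default_factory=SlicConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


_SECTIONS = {
    "scene": SceneConfig,
    "slic": SlicConfig,
    "features": FeatureConfig,
    "train": TrainConfig,
    "pipeline": PipelineConfig,
}

# tuple-valued dataclass fields arrive from YAML as lists
_TUPLE_FIELDS = {
    "ear_axis_range", "glcm_offsets", "glcm_stats", "c_grid", "gamma_grid",
}


def _build_section(cls, raw: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}; expected {SCHEMA_VERSION}")
    top_allowed = {"seed", "n_scenes"} | set(_SECTIONS)
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {"schema_version": version}
    for key in ("seed", "n_scenes"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name] or {}
            if not isinstance(section, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, f"section {name!r}")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration; load_config round-trips it."""
    data = asdict(config)
    for section in _SECTIONS:
        data[section] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in data[section].items()
        }
        for k, v in data[section].items():
            if isinstance(v, list):
                data[section][k] = [list(x) if isinstance(x, tuple) else x for x in v]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def with_seed(config: RunConfig, seed: int) -> RunConfig:
    """Propagate one global seed into the seeded sections."""
    return replace(
        config,
        seed=seed,
        scene=replace(config.scene, seed=seed),
        train=replace(config.train, seed=seed),
    )
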