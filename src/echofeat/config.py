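"""Run configuration: every tunable of the feature pipeline, with defaults.

An empty config is valid (all defaults are fully specified); unknown keys
are rejected so typos fail loudly rather than silently falling back.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ValidationError


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class MarginConfig:
    band_width: int = 5


@dataclass(frozen=True)
class LobulationConfig:
    median_frame: int = 21
    poly_degree: int = 20


@dataclass(frozen=True)
class SpiculesConfig:
    n_resample: int = 0  # 0 = use the raw traced boundary sequence


@dataclass(frozen=True)
class CalcConfig:
    alpha: float = 0.5
    struct_radius: int = 1
    min_blob_px: int = 4
    connectivity: int = 8
    morph_order: str = "close"


@dataclass(frozen=True)
class TextureConfig:
    L_s: int = 16
    L_g: int = 16
    gm_scale: str = "normalized"
    quantization: str = "fixed"


@dataclass(frozen=True)
class StatsConfig:
    variant: str = "pooled"


@dataclass(frozen=True)
class RunConfig:
    margin: MarginConfig = field(default_factory=MarginConfig)
    lobulation: LobulationConfig = field(default_factory=LobulationConfig)
    spicules: SpiculesConfig = field(default_factory=SpiculesConfig)
    calc: CalcConfig = field(default_factory=CalcConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "margin": MarginConfig, "lobulation": LobulationConfig,
        "spicules": SpiculesConfig, "calc": CalcConfig,
        "texture": TextureConfig, "stats": StatsConfig,
    }

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data.pop(name) or {})
        for scalar in ("seed", "log_level"):
            if scalar in data:
                kwargs[scalar] = data.pop(scalar)
        if data:
            raise ValidationError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
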