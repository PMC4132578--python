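"""Configuration loading and validation (YAML).

A :class:`ModelConfig` bundles every tunable of the pipeline: segmentation
thresholds, saliency weights, skin model, working-memory and tracker
settings, CFG defaults and evaluation parameters.  Unknown keys are
rejected with an error naming the key; omitted keys fall back to the
working defaults (tau_color = 50, tau_percep = 100, equal weights 1/7,
alignment gap −1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .saliency import SaliencyWeights, SkinModel
from .segmentation import GroupingParams


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AttentionParams:
    capacity: int = 4
    max_age: int | None = None  # WM entries immortal unless tracking kills them
    iou_threshold: float = 0.3
    lost_track_threshold: float = 0.5
    fovea_padding: int = 8  # px added around the attended bbox
    min_fovea: tuple[int, int] = (16, 16)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ConfigError("attention.capacity must be >= 1")
        if not (0.0 <= self.iou_threshold <= 1.0):
            raise ConfigError("attention.iou_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class CfgDefaults:
    num_rings: int = 2
    ring_scale: int = 2


@dataclass(frozen=True)
class EvalParams:
    gap: float = -0.5
    density_sigma: float = 0.0


@dataclass(frozen=True)
class ModelConfig:
    grouping: GroupingParams = field(default_factory=GroupingParams)
    weights: SaliencyWeights = field(default_factory=SaliencyWeights)
    skin: SkinModel = field(default_factory=SkinModel)
    attention: AttentionParams = field(default_factory=AttentionParams)
    cfg: CfgDefaults = field(default_factory=CfgDefaults)
    evaluation: EvalParams = field(default_factory=EvalParams)
    seed: int = 0

    def describe(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "grouping": GroupingParams,
    "weights": SaliencyWeights,
    "skin": SkinModel,
    "attention": AttentionParams,
    "cfg": CfgDefaults,
    "evaluation": EvalParams,
}
_TUPLE_FIELDS = {"values", "mean", "cov", "min_fovea"}


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key '{name}.{sorted(unknown)[0]}' (known: {sorted(known)})"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def config_from_dict(data: dict | None) -> ModelConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key '{sorted(unknown)[0]}'")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data[name])
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = data["seed"]
    return ModelConfig(**kwargs)


def load_config(path: str | None) -> ModelConfig:
    """Load a YAML config file; ``None`` or an empty file yields defaults."""
    if path is None:
        return ModelConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(config: ModelConfig, path: str) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(config.describe()), fh, sort_keys=True)
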