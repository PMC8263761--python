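"""Structured run configuration (YAML) binding the model blocks together."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .farm import FarmConfig
from .forcing import SyntheticForcingSpec
from .params import GrowthParameters, PumpSetting, ReactorGeometry

__all__ = ["RunConfig", "load_config", "default_config_yaml"]


@dataclass(frozen=True)
class ScenarioBlock:
    """Scenario sweep: seasons, pump flows, dilution ratios, sizing threshold."""

    seasons: tuple[str, ...] = ("winter", "spring", "summer", "autumn")
    Q_p: tuple[float, ...] = (460.0,)
    d: tuple[float, ...] = (0.0,)
    threshold: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration with model defaults baked in."""

    growth: GrowthParameters = field(default_factory=GrowthParameters)
    geometry: ReactorGeometry = field(default_factory=ReactorGeometry)
    farm: FarmConfig = field(default_factory=FarmConfig)
    forcing_spec: SyntheticForcingSpec = field(default_factory=SyntheticForcingSpec)
    scenario: ScenarioBlock = field(default_factory=ScenarioBlock)
    forcing_path: str | None = None
    experiments_path: str | None = None
    output_dir: str = "results"
    seed: int = 0
    verbose: bool = False

    def digest(self) -> str:
        """Stable hash of the configuration (logged for reproducibility)."""
        payload = json.dumps(_as_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def _build(cls, data: dict):
    """Instantiate a (frozen) dataclass from a plain dict, recursing into
    nested dataclass fields; unknown keys are an error."""
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = field_map[name].type
        if isinstance(value, dict):
            nested = _NESTED.get((cls, name))
            if nested is not None:
                value = _build(nested, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "growth"): GrowthParameters,
    (RunConfig, "geometry"): ReactorGeometry,
    (RunConfig, "farm"): FarmConfig,
    (RunConfig, "forcing_spec"): SyntheticForcingSpec,
    (RunConfig, "scenario"): ScenarioBlock,
    (FarmConfig, "pump"): PumpSetting,
    (FarmConfig, "geometry"): ReactorGeometry,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    return _build(RunConfig, data)


def default_config_yaml() -> str:
    """The full default configuration as a YAML document."""
    return yaml.safe_dump(_as_dict(RunConfig()), sort_keys=False)
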