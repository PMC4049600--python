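"""Pipeline configuration: a validated, nested, YAML-backed structure.

Unknown keys are rejected so that typos fail before any stage runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass(frozen=True)
class IcaSettings:
    n_components: int = 8
    n_runs: int = 10
    k_subject: int | None = None
    seed: int | None = None          # defaults to the master seed
    max_sweeps: int = 512
    tol: float = 1e-6


@dataclass(frozen=True)
class HrfSettings:
    step: float = 0.1
    onset_shift: float = 1.0
    dispersion_increment: float = 0.01
    convolve_motion: bool = True


@dataclass(frozen=True)
class BehaviorSettings:
    exclusion_rule: str = "either"   # "either" | "both"


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    holm: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "nback_ica_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ica: IcaSettings = field(default_factory=IcaSettings)
    hrf: HrfSettings = field(default_factory=HrfSettings)
    behavior: BehaviorSettings = field(default_factory=BehaviorSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def __post_init__(self) -> None:
        if self.behavior.exclusion_rule not in ("either", "both"):
            raise ValueError("exclusion_rule must be 'either' or 'both'")
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "simulation", "ica", "hrf", "behavior", "stats"):
            sub_cls = {"simulation": SimulationConfig, "ica": IcaSettings,
                       "hrf": HrfSettings, "behavior": BehaviorSettings,
                       "stats": StatsSettings}[f.name]
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(sub_cls, value, f"{path}.{key}")
        elif key == "grid_dims" and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline config."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _build(PipelineConfig, data, "")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
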