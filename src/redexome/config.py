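"""YAML pipeline configuration.

One document drives the whole pipeline; unknown keys are rejected so
typos fail loudly. CLI flags override file values; all randomness flows
from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .caller import DEFAULT_LOW_DEPTH_THRESHOLD
from .errors import ConfigError
from .simulate import SimulationConfig

__all__ = ["CallerConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class CallerConfig:
    min_flank: int = 10
    low_depth_threshold: float = DEFAULT_LOW_DEPTH_THRESHOLD


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    catalogue: str | None = None  # None -> shipped default catalogue
    outdir: str = "redexome_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)


def _build(cls: type, data: Mapping[str, Any], context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline config; ``seed`` (when given) overrides the file."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = dict(loaded)
    sim_data = dict(data.pop("simulation", {}) or {})
    caller_data = dict(data.pop("caller", {}) or {})
    if seed is not None:
        data["seed"] = seed
    config = _build(PipelineConfig, data, "pipeline config")
    sim_data.setdefault("seed", config.seed)
    sim_data.setdefault("min_flank", caller_data.get("min_flank", 10))
    simulation = _build(SimulationConfig, sim_data, "simulation block")
    caller = _build(CallerConfig, caller_data, "caller block")
    return PipelineConfig(
        seed=config.seed,
        catalogue=config.catalogue,
        outdir=config.outdir,
        simulation=simulation,
        caller=caller,
    )
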