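"""Run configuration: a strict key-value (YAML) file mapped onto the
engine, simulation and analysis parameter dataclasses.

Unknown keys are rejected so that typos cannot silently fall back to
defaults; a seed is mandatory for any stochastic command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import time
from pathlib import Path
from typing import Optional, Union

import yaml

from .engine import EngineConfig
from .simulate import EngagementModel, SimulationParams

__all__ = ["ConfigError", "RunConfig", "load_config", "params_hash"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    seed: int
    engine: EngineConfig
    simulation: SimulationParams
    n_app: int = 104
    n_usual: int = 105
    detail: str = "outcomes"
    alpha: float = 0.05
    out_dir: str = "out"


def _parse_active_window(raw: str) -> tuple[time, time]:
    try:
        start_s, end_s = raw.split("-")
        return time.fromisoformat(start_s.strip()), time.fromisoformat(end_s.strip())
    except ValueError as exc:
        raise ConfigError(f"bad active_window {raw!r} (expected 'HH:MM-HH:MM'): {exc}")


def _build(cls, section: dict, name: str, converters=None):
    converters = converters or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - set(converters) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if key in converters:
            dest, fn = converters[key]
            kwargs[dest] = fn(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from None


_TOP_KEYS = {"seed", "engine", "simulation", "engagement", "n_app", "n_usual",
             "detail", "alpha", "out_dir"}


def load_config(path: Union[str, Path], seed_override: Optional[int] = None) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")

    seed = seed_override if seed_override is not None else raw.get("seed")
    if seed is None:
        raise ConfigError(f"{path}: a seed is required (key 'seed' or --seed)")

    engine = _build(
        EngineConfig,
        raw.get("engine", {}) or {},
        "engine",
        converters={"active_window": ("active_window", _parse_active_window)},
    )
    engagement = _build(EngagementModel, raw.get("engagement", {}) or {}, "engagement")
    sim_section = dict(raw.get("simulation", {}) or {})
    simulation = _build(
        SimulationParams,
        {**sim_section, "engagement": engagement, "engine_config": engine},
        "simulation",
    )
    return RunConfig(
        seed=int(seed),
        engine=engine,
        simulation=simulation,
        n_app=int(raw.get("n_app", 104)),
        n_usual=int(raw.get("n_usual", 105)),
        detail=str(raw.get("detail", "outcomes")),
        alpha=float(raw.get("alpha", 0.05)),
        out_dir=str(raw.get("out_dir", "out")),
    )


def params_hash(config: RunConfig) -> str:
    """Stable digest of every parameter that affects outputs."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, time):
            return obj.isoformat()
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
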