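"""Run configuration: typed stage blocks, strict validation, full resolution.

A RunConfig is a YAML file with a `stages` list and optional per-stage blocks
(`frap_sim`, `em_sim`, `timelapse_sim`, `frap_fit`, `gold_detect`,
`morpho`). Unknown keys are rejected; every run writes the fully-resolved
config (all defaults materialized) beside its outputs. The single global seed
expands into deterministic per-stage sub-seeds via sha256 of "seed:stage".
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .sim.em_sim import EmSimParams
from .sim.frap_sim import FrapSimParams
from .sim.timelapse_sim import TimelapseSimParams

KNOWN_STAGES = (
    "simulate_frap", "simulate_em", "simulate_timelapse",
    "frap_fit", "gold_detect", "morpho_measure",
)


class ConfigError(ValueError):
    pass


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    n_frap_curves: int = 30
    frap_sim: dict = field(default_factory=dict)
    em_sim: dict = field(default_factory=dict)
    timelapse_sim: dict = field(default_factory=dict)
    frap_fit: dict = field(default_factory=dict)  # e.g. {"tau2_mode": "condition_mean"}
    gold_detect: dict = field(default_factory=dict)  # e.g. {"exclusion_radius_nm": 12.0}
    morpho: dict = field(default_factory=dict)
    verbosity: str = "info"


_PARAM_TYPES = {
    "frap_sim": FrapSimParams,
    "em_sim": EmSimParams,
    "timelapse_sim": TimelapseSimParams,
}
_FREE_BLOCKS = {
    "frap_fit": {"tau2_mode", "explicit_tau2"},
    "gold_detect": {"exclusion_radius_nm", "threshold_12nm", "threshold_6nm"},
    "morpho": {"min_area_px", "gate_um", "fragment_count_min",
               "fragment_max_area_fraction", "condensed_sphericity_min"},
}


def _check_block(name: str, block: dict) -> None:
    if name in _PARAM_TYPES:
        allowed = {f.name for f in dataclasses.fields(_PARAM_TYPES[name])} - {"roi"}
    else:
        allowed = _FREE_BLOCKS[name]
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for stage in cfg.stages:
        if stage not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {stage!r}; known: {KNOWN_STAGES}")
    for name in (*_PARAM_TYPES, *_FREE_BLOCKS):
        _check_block(name, getattr(cfg, name))
    return cfg


def resolve_config(cfg: RunConfig) -> dict:
    """Materialize every default into a plain dict (total resolution)."""
    out = dataclasses.asdict(cfg)
    for name, cls in _PARAM_TYPES.items():
        block = dict(getattr(cfg, name))
        block.setdefault("seed", derive_seed(cfg.seed, name))
        params = cls(**block)
        d = dataclasses.asdict(params)
        d.pop("roi", None)
        out[name] = d
    for name, allowed in _FREE_BLOCKS.items():
        block = dict(getattr(cfg, name))
        defaults = {
            "frap_fit": {"tau2_mode": "condition_mean", "explicit_tau2": None},
            "gold_detect": {"exclusion_radius_nm": 12.0, "threshold_12nm": None,
                            "threshold_6nm": None},
            "morpho": {"min_area_px": 4, "gate_um": 10.0, "fragment_count_min": 6,
                       "fragment_max_area_fraction": 0.5, "condensed_sphericity_min": 0.9},
        }[name]
        out[name] = {**defaults, **block}
    return out


def save_resolved_config(resolved: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
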