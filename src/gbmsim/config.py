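"""YAML configuration loading and validation.

One config dialect (YAML, ``schema: 1``) is frozen as the public contract.
Defaults fill the published parameter column for the chosen model; motility
values outside the published ranges produce warnings, unknown keys are
errors with their full key path.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .grid import Grid
from .mri import RadiologyThresholds
from .params import GOG_DEFAULTS, PARAM_RANGES, SINGLE_CELL_DEFAULTS, ModelParams
from .solver import SeedSpec, SimulationConfig

__all__ = ["load_config", "config_to_dict", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed configuration; no partial state is constructed."""


_SECTIONS = {
    "schema", "model", "params", "grid", "seed", "simulation", "thresholds",
}
_PARAM_KEYS = {"delta", "eta", "tau", "gamma", "sigma", "omega",
               "alpha", "beta", "phi", "switch_steepness", "necrosis_rate_max"}
_GRID_KEYS = {"nx", "ny", "h"}
_SEED_KEYS = {"shape", "amplitude", "radius_mm", "center", "cutoff_sigmas"}
_SIM_KEYS = {"dt", "t_max", "snapshot_interval", "store_state_interval",
             "rng_seed", "reaction_substeps", "c_react", "dt_max"}
_THRESH_KEYS = {"flair_C", "vasc_C", "rad_necrosis_B", "path_necrosis_B"}


def _check_keys(section: str, data: Dict[str, Any], allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'")


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a simulation config; raises ConfigError on problems."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: Dict[str, Any]) -> SimulationConfig:
    _check_keys("<root>", raw, _SECTIONS)
    schema = raw.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {schema}")

    model = raw.get("model", "single_cell")
    if model not in ("single_cell", "gog"):
        raise ConfigError(f"model must be single_cell or gog, got {model!r}")

    pdata = dict(raw.get("params") or {})
    _check_keys("params", pdata, _PARAM_KEYS)
    try:
        params = (ModelParams.single_cell(**pdata) if model == "single_cell"
                  else ModelParams.gog(**pdata))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"params: {exc}") from exc
    for name, (lo, hi) in PARAM_RANGES.items():
        v = getattr(params, name)
        if not (lo <= v <= hi):
            warnings.warn(
                f"params.{name} = {v:g} is outside the published range "
                f"[{lo:g}, {hi:g}]", stacklevel=2)

    gdata = dict(raw.get("grid") or {})
    _check_keys("grid", gdata, _GRID_KEYS)
    try:
        grid = Grid(**gdata)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"grid: {exc}") from exc

    sdata = dict(raw.get("seed") or {})
    _check_keys("seed", sdata, _SEED_KEYS)
    if "center" in sdata and sdata["center"] is not None:
        sdata["center"] = tuple(sdata["center"])
    try:
        seed = SeedSpec(**sdata)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"seed: {exc}") from exc

    tdata = dict(raw.get("thresholds") or {})
    _check_keys("thresholds", tdata, _THRESH_KEYS)
    try:
        thresholds = RadiologyThresholds(**tdata)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"thresholds: {exc}") from exc

    simdata = dict(raw.get("simulation") or {})
    _check_keys("simulation", simdata, _SIM_KEYS)
    try:
        return SimulationConfig(grid=grid, params=params, seed=seed,
                                thresholds=thresholds, **simdata)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc


def config_to_dict(cfg: SimulationConfig) -> Dict[str, Any]:
    """Canonical round-trippable dict form (also hashed into run manifests)."""
    params = cfg.params.to_dict()
    params.pop("model_kind")
    if cfg.params.model_kind == "single_cell":
        for k in ("alpha", "beta", "phi"):
            params.pop(k)
    return {
        "schema": SCHEMA_VERSION,
        "model": cfg.params.model_kind,
        "params": params,
        "grid": {"nx": cfg.grid.nx, "ny": cfg.grid.ny, "h": cfg.grid.h},
        "seed": {
            "shape": cfg.seed.shape, "amplitude": cfg.seed.amplitude,
            "radius_mm": cfg.seed.radius_mm,
            "center": list(cfg.seed.center) if cfg.seed.center else None,
            "cutoff_sigmas": cfg.seed.cutoff_sigmas,
        },
        "thresholds": {
            "flair_C": cfg.thresholds.flair_C, "vasc_C": cfg.thresholds.vasc_C,
            "rad_necrosis_B": cfg.thresholds.rad_necrosis_B,
            "path_necrosis_B": cfg.thresholds.path_necrosis_B,
        },
        "simulation": {
            "dt": cfg.dt, "t_max": cfg.t_max,
            "snapshot_interval": cfg.snapshot_interval,
            "store_state_interval": cfg.store_state_interval,
            "rng_seed": cfg.rng_seed,
            "reaction_substeps": cfg.reaction_substeps,
            "c_react": cfg.c_react, "dt_max": cfg.dt_max,
        },
    }
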