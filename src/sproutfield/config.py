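"""Structured configuration with defaults and strict schema validation.

An empty config resolves to the default calibration: 200x200 grid at
3.85 um per pixel, dt = 1e-3 in-silico, unit mobility and interface width,
linear chemoattractant gradient 0.1*y + 0.3, synthetic 40-um-pore matrix,
gamma = 0.5 ECM coupling.  Unknown keys are rejected with their full path.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "dump_config"]

DEFAULT_CONFIG: dict = {
    "grid": {
        "nx": 200,
        "ny": 200,
        "dx_um": 3.85,
        "time_unit_h": 2.75e-3,
        "dt": 1e-3,
    },
    "model": {
        "M": 1.0,
        "eps": 1.0,
        "dt": 1e-3,
        "env_grouping": "additive",
        "overshoot_tol": 0.1,
    },
    "gradient": {
        "profile": "linear",
        "alpha": 0.1,
        "beta": 0.3,
        "axis": 1,
        "direction": -1,
        "peak_start": 0.1,
        "peak_level": 0.5,
        "peak_pos_px": 100.0,
    },
    "ecm": {
        "source": "synthetic",  # synthetic | image
        "image_path": None,
        "porosity": 0.25,
        "target_mean_pore_um": 40.0,
        "correlation_length_px": None,
        "seed": 0,
    },
    "env": {
        "gamma": 0.5,
        "floor": 0.0,
    },
    "path": {
        "enabled": False,
        "waypoints": None,
        "width_px": 12.0,
    },
    "degradation": {
        "enabled": False,
        "sensing_radius_px": 10.0,
        "power": 0.2,
        "sigma_px": 5.0,
        "cadence_steps": None,
        "heading_halfangle_deg": 60.0,
        "n_headings": 9,
    },
    "scenario": None,
    "seed": 0,
    "schedule_hours": [2.75, 27.5, 55.0, 96.25],
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict):
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a partial config onto the defaults and validate it."""
    cfg = _merge(DEFAULT_CONFIG, user or {})
    # construct the specs eagerly so invalid values fail here with context
    from .grid_env import ChemotacticSpec, GridSpec
    from .solver import ModelParams

    GridSpec(**cfg["grid"])
    g = cfg["gradient"]
    ChemotacticSpec(**g)
    try:
        ModelParams(**cfg["model"])
    except ValueError as e:
        raise ConfigError(f"model: {e}") from e
    if cfg["ecm"]["source"] not in ("synthetic", "image"):
        raise ConfigError("ecm.source must be 'synthetic' or 'image'")
    if cfg["ecm"]["source"] == "image" and not cfg["ecm"]["image_path"]:
        raise ConfigError("ecm.image_path required when ecm.source = image")
    return cfg


def load_config(path) -> dict:
    """Read a YAML config file, fill defaults, and validate."""
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    return resolve_config(user)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
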