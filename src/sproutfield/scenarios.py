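"""Builders for the canonical in-silico experiments.

Each builder assembles a :class:`Scenario` — grid, environment, initial
phase state, reservoir, model and (optionally) degradation parameters plus
a snapshot schedule — that is fully reconstructible from its config dict
and seed.  The six canonical setups:

``pocket``            a single rectangular pore pocket in solid matrix with
                      a peaked chemoattractant; ``contact`` controls whether
                      the pocket touches the endothelium.
``open_path``         porous matrix with a carved corridor, linear gradient,
                      spherical-cap endothelium at the high-y edge.
``sphere_path``       small spherical cell reservoir on the corridor axis.
``sphere_degradation``  spherical reservoir, no carved path, matrix
                      degradation enabled.
``static_tip``        frozen tip cell used to demonstrate the MMP rule.
``no_gradient``       uniform baseline chemoattractant confined to pore
                      space; no directional cue, degradation off.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .degradation import DegradationParams, degradation_event
from .grid_env import (
    ChemotacticSpec,
    EcmGenSpec,
    EnvironmentLandscape,
    GridSpec,
    PathSpec,
    ScalarField,
    carve_open_path,
    compose_environment,
    generate_synthetic_ecm,
    load_hydrogel_image,
    make_gradient,
)
from .solver import ModelParams, PhaseState, ReservoirSpec

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "build_scenario",
    "pocket_scenario",
    "open_path_scenario",
    "sphere_path_scenario",
    "sphere_degradation_scenario",
    "static_tip_scenario",
    "no_gradient_scenario",
    "run_static_tip_events",
    "flat_front_phi",
    "cap_phi",
    "sphere_phi",
]

SCENARIO_NAMES = (
    "pocket_contact",
    "pocket_distant",
    "open_path",
    "sphere_path",
    "sphere_degradation",
    "static_tip",
    "no_gradient",
)

_SQRT2 = float(np.sqrt(2.0))

# geometry defaults shared by the builders (pixels on the default grid)
FRONT_DEPTH_PX = 10
CAP_RADIUS_PX = 30
SPHERE_RADIUS_PX = 15
PATH_WIDTH_PX = 12.0
POCKET_SIZE_PX = 50


@dataclass
class Scenario:
    """A complete, reproducible simulation setup."""

    name: str
    grid: GridSpec
    env: EnvironmentLandscape
    initial: PhaseState
    reservoir: ReservoirSpec | None
    model: ModelParams
    degradation: DegradationParams | None
    schedule_hours: tuple[float, ...]
    config: dict = field(default_factory=dict)

    def run(self, engine: str = "fast", progress: bool = False):
        from .solver import run_simulation

        return run_simulation(
            self.env,
            self.model,
            self.grid,
            self.reservoir,
            self.initial,
            self.schedule_hours,
            degradation=self.degradation,
            engine=engine,
            progress=progress,
        )


def flat_front_phi(grid: GridSpec, depth_px: int = FRONT_DEPTH_PX, eps: float = 1.0) -> np.ndarray:
    """Flat endothelium occupying the last ``depth_px`` rows of the y axis."""
    j = np.arange(grid.ny, dtype=float)
    j0 = grid.ny - 1 - depth_px
    prof = np.tanh((j - j0) / (_SQRT2 * eps))
    return np.broadcast_to(prof[None, :], grid.shape).copy()


def _radial_phi(grid: GridSpec, center: tuple[float, float], radius: float, eps: float) -> np.ndarray:
    ii, jj = np.meshgrid(
        np.arange(grid.nx, dtype=float), np.arange(grid.ny, dtype=float), indexing="ij"
    )
    r = np.hypot(ii - center[0], jj - center[1])
    return np.tanh((radius - r) / (_SQRT2 * eps))


def cap_phi(grid: GridSpec, cx: float, radius: float = CAP_RADIUS_PX, eps: float = 1.0) -> np.ndarray:
    """Half-disc endothelium cap attached to the high-y edge."""
    return _radial_phi(grid, (cx, grid.ny - 1), radius, eps)


def sphere_phi(
    grid: GridSpec, center: tuple[float, float], radius: float = SPHERE_RADIUS_PX, eps: float = 1.0
) -> np.ndarray:
    """Circular cell blob (the 2-D section of a spherical reservoir)."""
    return _radial_phi(grid, center, radius, eps)


def _edge_reservoir(grid: GridSpec, rows: int = 4) -> ReservoirSpec:
    mask = np.zeros(grid.shape, dtype=bool)
    mask[:, grid.ny - rows :] = True
    return ReservoirSpec(mask, 1.0)


def _core_reservoir(
    grid: GridSpec, center: tuple[float, float], radius: float, margin: float = 3.0
) -> ReservoirSpec:
    """Dirichlet mask over the bulk core of an initial blob.

    The pinned region stops ``margin`` pixels short of the nominal radius so
    the diffuse interface of the initial condition is left free to move.
    """
    ii, jj = np.meshgrid(
        np.arange(grid.nx, dtype=float), np.arange(grid.ny, dtype=float), indexing="ij"
    )
    r = np.hypot(ii - center[0], jj - center[1])
    return ReservoirSpec(r <= radius - margin, 1.0)


def _make_hydrogel(grid: GridSpec, cfg: dict) -> ScalarField:
    source = cfg.get("source", "synthetic")
    if source == "image":
        return load_hydrogel_image(cfg["image_path"], grid)
    spec = EcmGenSpec(
        porosity=cfg.get("porosity", 0.25),
        target_mean_pore_um=cfg.get("target_mean_pore_um", 40.0),
        correlation_length_px=cfg.get("correlation_length_px"),
        seed=cfg.get("seed", 0),
    )
    return generate_synthetic_ecm(spec, grid)


def _grid_from(cfg: dict) -> GridSpec:
    return GridSpec(**cfg.get("grid", {}))


def _model_from(cfg: dict) -> ModelParams:
    return ModelParams(**cfg.get("model", {}))


def pocket_scenario(
    contact: bool = True, grid: GridSpec | None = None, model: ModelParams | None = None
) -> Scenario:
    """Single pore pocket in solid matrix with a peaked chemoattractant.

    ``contact=True`` places the pocket flush against the endothelium so the
    chemoattractant reaches the cell front; ``contact=False`` leaves a
    dense-matrix gap in which the composite environment is zero, which
    suppresses sprouting.
    """
    grid = grid or GridSpec()
    model = model or ModelParams()
    eps = model.eps
    front_j = grid.ny - 1 - FRONT_DEPTH_PX
    # geometry shrinks proportionally on sub-default grids
    pocket = min(POCKET_SIZE_PX, grid.ny // 4)
    gap = 0 if contact else min(40, grid.ny // 5)
    j_hi = front_j - gap
    j_lo = j_hi - pocket
    if j_lo < 0:
        raise ValueError("grid too small for the pocket geometry")
    half_w = pocket // 2
    i_lo, i_hi = grid.nx // 2 - half_w, grid.nx // 2 + half_w

    h = np.ones(grid.shape)
    h[i_lo:i_hi, j_lo:j_hi] = 0.0

    peak_u = (grid.ny - 1) - 0.5 * (j_lo + j_hi)  # pocket centre, cell-edge coords
    chemo = ChemotacticSpec(
        profile="peaked", peak_start=0.1, peak_level=0.5, peak_pos_px=float(peak_u)
    )
    nu_c = make_gradient(chemo, grid)
    env = compose_environment(nu_c, ScalarField(h, "hydrogel_density"))

    phi = flat_front_phi(grid, FRONT_DEPTH_PX, eps)
    name = "pocket_contact" if contact else "pocket_distant"
    return Scenario(
        name=name,
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=_edge_reservoir(grid),
        model=model,
        degradation=None,
        schedule_hours=(2.75, 13.75, 27.5),
        config={"scenario": name, "grid": _grid_cfg(grid), "model": _model_cfg(model)},
    )


def _porous_env(
    grid: GridSpec, seed: int, ecm: dict | None, carve: bool
) -> EnvironmentLandscape:
    ecm_cfg = dict(ecm or {})
    ecm_cfg.setdefault("seed", seed)
    h = _make_hydrogel(grid, ecm_cfg)
    if carve:
        path = PathSpec(
            waypoints=((grid.nx / 2, grid.ny - 1.0), (grid.nx / 2, 0.0)),
            width_px=PATH_WIDTH_PX,
        )
        h = carve_open_path(h, path)
    nu_c = make_gradient(ChemotacticSpec(profile="linear"), grid)
    return compose_environment(nu_c, h)


def open_path_scenario(
    grid: GridSpec | None = None,
    seed: int = 0,
    ecm: dict | None = None,
    model: ModelParams | None = None,
) -> Scenario:
    """Porous matrix + carved corridor, cap endothelium, linear gradient."""
    grid = grid or GridSpec()
    model = model or ModelParams()
    env = _porous_env(grid, seed, ecm, carve=True)
    cx = grid.nx / 2
    phi = cap_phi(grid, cx, CAP_RADIUS_PX, model.eps)
    res = _core_reservoir(grid, (cx, grid.ny - 1), CAP_RADIUS_PX)
    return Scenario(
        name="open_path",
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=res,
        model=model,
        degradation=None,
        schedule_hours=(2.75, 27.5, 55.0, 96.25),
        config={
            "scenario": "open_path",
            "seed": seed,
            "ecm": dict(ecm or {}),
            "grid": _grid_cfg(grid),
            "model": _model_cfg(model),
        },
    )


def _sphere_center(grid: GridSpec) -> tuple[float, float]:
    return (grid.nx / 2, grid.ny - 1 - 25.0)


def sphere_path_scenario(
    grid: GridSpec | None = None,
    seed: int = 0,
    ecm: dict | None = None,
    model: ModelParams | None = None,
) -> Scenario:
    """Small spherical reservoir migrating through a carved corridor."""
    grid = grid or GridSpec()
    model = model or ModelParams()
    env = _porous_env(grid, seed, ecm, carve=True)
    center = _sphere_center(grid)
    phi = sphere_phi(grid, center, SPHERE_RADIUS_PX, model.eps)
    res = _core_reservoir(grid, center, SPHERE_RADIUS_PX)
    return Scenario(
        name="sphere_path",
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=res,
        model=model,
        degradation=None,
        schedule_hours=(2.75, 27.5, 55.0, 96.25),
        config={
            "scenario": "sphere_path",
            "seed": seed,
            "ecm": dict(ecm or {}),
            "grid": _grid_cfg(grid),
            "model": _model_cfg(model),
        },
    )


def sphere_degradation_scenario(
    grid: GridSpec | None = None,
    seed: int = 0,
    ecm: dict | None = None,
    model: ModelParams | None = None,
    degradation: DegradationParams | None = None,
) -> Scenario:
    """Spherical reservoir, no carved path, matrix degradation enabled."""
    grid = grid or GridSpec()
    model = model or ModelParams()
    degradation = degradation or DegradationParams()
    env = _porous_env(grid, seed, ecm, carve=False)
    center = _sphere_center(grid)
    phi = sphere_phi(grid, center, SPHERE_RADIUS_PX, model.eps)
    res = _core_reservoir(grid, center, SPHERE_RADIUS_PX)
    return Scenario(
        name="sphere_degradation",
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=res,
        model=model,
        degradation=degradation,
        schedule_hours=(2.75, 27.5, 55.0, 82.5),
        config={
            "scenario": "sphere_degradation",
            "seed": seed,
            "ecm": dict(ecm or {}),
            "grid": _grid_cfg(grid),
            "model": _model_cfg(model),
            "degradation": _degr_cfg(degradation),
        },
    )


def no_gradient_scenario(
    grid: GridSpec | None = None,
    seed: int = 0,
    ecm: dict | None = None,
    model: ModelParams | None = None,
    baseline: float = 0.3,
) -> Scenario:
    """Uniform baseline chemoattractant confined to pore space; no cue.

    Cells at the endothelium can enter adjacent pores (where the baseline
    level activates them) but receive no long-range directional signal.
    """
    grid = grid or GridSpec()
    model = model or ModelParams()
    ecm_cfg = dict(ecm or {})
    ecm_cfg.setdefault("seed", seed)
    h = _make_hydrogel(grid, ecm_cfg)
    nu_vals = np.where(h.values < 0.5, baseline, 0.0)
    env = compose_environment(ScalarField(nu_vals, "nu_c"), h)
    phi = flat_front_phi(grid, FRONT_DEPTH_PX, model.eps)
    return Scenario(
        name="no_gradient",
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=_edge_reservoir(grid),
        model=model,
        degradation=None,
        schedule_hours=(12.0, 24.0, 48.0),
        config={
            "scenario": "no_gradient",
            "seed": seed,
            "ecm": ecm_cfg,
            "grid": _grid_cfg(grid),
            "model": _model_cfg(model),
        },
    )


def static_tip_scenario(
    grid: GridSpec | None = None,
    seed: int = 0,
    ecm: dict | None = None,
    degradation: DegradationParams | None = None,
) -> Scenario:
    """Frozen tip cell demonstrating repeated MMP deposition.

    The phase field never advances; use :func:`run_static_tip_events` to
    apply a number of degradation events and collect the hydrogel states.
    """
    grid = grid or GridSpec()
    model = ModelParams()
    degradation = degradation or DegradationParams(cadence_steps=1)
    env = _porous_env(grid, seed, ecm, carve=False)
    center = _sphere_center(grid)
    phi = sphere_phi(grid, center, SPHERE_RADIUS_PX, model.eps)
    return Scenario(
        name="static_tip",
        grid=grid,
        env=env,
        initial=PhaseState(ScalarField(phi, "phi")),
        reservoir=None,
        model=model,
        degradation=degradation,
        schedule_hours=(),
        config={
            "scenario": "static_tip",
            "seed": seed,
            "ecm": dict(ecm or {}),
            "grid": _grid_cfg(grid),
            "degradation": _degr_cfg(degradation),
        },
    )


def run_static_tip_events(scenario: Scenario, n_events: int) -> list[np.ndarray]:
    """Apply n degradation events with a frozen phase; return hydrogel states.

    The returned list holds n_events + 1 hydrogel fields (before the first
    event and after each event).  The tip never moves.
    """
    env = scenario.env.copy()
    states = [env.hydrogel.values.copy()]
    for _ in range(n_events):
        env, _decision = degradation_event(scenario.initial, env, scenario.degradation)
        states.append(env.hydrogel.values.copy())
    return states


def _grid_cfg(grid: GridSpec) -> dict:
    return {
        "nx": grid.nx,
        "ny": grid.ny,
        "dx_um": grid.dx_um,
        "time_unit_h": grid.time_unit_h,
        "dt": grid.dt,
    }


def _model_cfg(model: ModelParams) -> dict:
    return {
        "M": model.M,
        "eps": model.eps,
        "dt": model.dt,
        "env_grouping": model.env_grouping,
        "overshoot_tol": model.overshoot_tol,
    }


def _degr_cfg(d: DegradationParams) -> dict:
    return {
        "sensing_radius_px": d.sensing_radius_px,
        "power": d.power,
        "sigma_px": d.sigma_px,
        "cadence_steps": d.cadence_steps,
        "heading_halfangle_deg": d.heading_halfangle_deg,
        "n_headings": d.n_headings,
        "score_tie_tol": d.score_tie_tol,
    }


def build_scenario(config: dict) -> Scenario:
    """Rebuild a Scenario from its config dict (the round-trip inverse)."""
    cfg = copy.deepcopy(config)
    name = cfg.get("scenario")
    grid = _grid_from(cfg)
    model = _model_from(cfg) if "model" in cfg else None
    seed = cfg.get("seed", 0)
    ecm = cfg.get("ecm")
    degr = (
        DegradationParams(**cfg["degradation"]) if cfg.get("degradation") else None
    )
    if name == "pocket_contact":
        return pocket_scenario(True, grid, model)
    if name == "pocket_distant":
        return pocket_scenario(False, grid, model)
    if name == "open_path":
        return open_path_scenario(grid, seed, ecm, model)
    if name == "sphere_path":
        return sphere_path_scenario(grid, seed, ecm, model)
    if name == "sphere_degradation":
        return sphere_degradation_scenario(grid, seed, ecm, model, degr)
    if name == "static_tip":
        return static_tip_scenario(grid, seed, ecm, degr)
    if name == "no_gradient":
        return no_gradient_scenario(grid, seed, ecm, model)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
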