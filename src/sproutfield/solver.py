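"""Conserved phase-field dynamics for collective cell migration.

The order parameter ``phi`` takes +1 in the cell phase and -1 in the
medium.  Its evolution couples a Cahn-Hilliard term (conserved double-well
gradient flow) to an environment effect acting through the interface-
localized interaction term ``B = eps * C0 * (phi**2 - 1)``::

    dphi/dt = M * lap(-phi + phi**3 - eps**2 * lap(phi))
              + 2 * phi * eps * C0 * B - eps**2 * lap(B)

Spatial derivatives use the five-point stencil with edge-replicated
(no-flux) closure; time integration is explicit Euler.  Cell reservoirs
(the endothelium) are Dirichlet regions re-pinned after every step.

Two groupings of the environment effect are available: ``additive`` (the
default, the environment term added outside the outer Laplacian, so it can
inject or remove phase) and ``conserved`` (the term folded into the
chemical potential inside the Laplacian, conserving total phi exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_env import EnvironmentLandscape, GridSpec, ScalarField, as_array

__all__ = [
    "ModelParams",
    "PhaseState",
    "ReservoirSpec",
    "Snapshot",
    "Trajectory",
    "InstabilityError",
    "stability_dt_limit",
    "laplacian_5pt",
    "interaction_term",
    "rhs",
    "apply_reservoir",
    "step",
    "free_energy",
    "tanh_interface",
    "run_simulation",
]


class InstabilityError(RuntimeError):
    """Raised when the explicit scheme leaves the admissible phi range."""

    def __init__(self, step_index: int, max_abs_phi: float):
        self.step_index = step_index
        self.max_abs_phi = max_abs_phi
        super().__init__(
            f"instability at step {step_index}: max|phi| = {max_abs_phi:.4g}"
        )


def stability_dt_limit(M: float = 1.0, eps: float = 1.0, dx: float = 1.0) -> float:
    """Safe explicit-Euler step for the biharmonic term: 0.8 * dx^4/(32 M eps^2)."""
    return 0.8 * dx**4 / (32.0 * M * eps**2)


@dataclass(frozen=True)
class ModelParams:
    """Mobility, interface width and stepping controls of the dynamics."""

    M: float = 1.0
    eps: float = 1.0
    dt: float = 1e-3
    env_grouping: str = "additive"  # additive | conserved
    overshoot_tol: float = 0.1
    #: The environment coupling acts only where 1 - phi**2 exceeds this, i.e.
    #: at resolved interfaces.  Round-off-scale deviations from the bulk
    #: would otherwise be amplified exponentially wherever C0 > 0, nucleating
    #: spurious cell mass far from any real front.
    interface_cutoff: float = 1e-3

    def __post_init__(self) -> None:
        if self.M <= 0 or self.eps <= 0 or self.dt <= 0:
            raise ValueError("M, eps and dt must be positive")
        if self.env_grouping not in ("additive", "conserved"):
            raise ValueError(f"unknown env_grouping {self.env_grouping!r}")
        limit = stability_dt_limit(self.M, self.eps)
        if self.dt > limit * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} exceeds the explicit stability guard {limit:.4g}"
            )


@dataclass
class PhaseState:
    """The phi field together with the simulation clock."""

    phi: ScalarField
    t_insilico: float = 0.0
    step_index: int = 0

    def copy(self) -> "PhaseState":
        return PhaseState(self.phi.copy(), self.t_insilico, self.step_index)


@dataclass
class ReservoirSpec:
    """Dirichlet region where phi is re-pinned to ``value`` after each step."""

    mask: np.ndarray
    value: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if abs(self.value) != 1.0:
            raise ValueError("reservoir value must be +1 or -1")


def laplacian_5pt(f: ScalarField | np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Five-point Laplacian with mirror (edge-replicate, no-flux) closure."""
    a = as_array(f)
    p = np.pad(a, 1, mode="edge")
    return (
        p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * a
    ) / dx**2


def interaction_term(
    phi: ScalarField | np.ndarray,
    C0: ScalarField | np.ndarray,
    eps: float = 1.0,
    cutoff: float = 0.0,
) -> np.ndarray:
    """Interface-localized environment coupling ``eps * C0 * (phi**2 - 1)``.

    Vanishes in both bulks (phi = +-1), so the environment acts only at the
    cell boundary.  Two regularizations keep that statement true for the
    discrete dynamics: phi is saturated to [-1, 1] before evaluation
    (outside the physical range the raw quadratic changes sign and couples
    the bulk phases to the environment, turning the benign overshoot of the
    explicit scheme into a runaway), and the term is zeroed where
    ``1 - phi**2 <= cutoff`` so round-off-scale bulk deviations cannot be
    amplified into spurious nucleation.  At resolved interfaces both forms
    coincide with the raw expression.
    """
    p = as_array(phi)
    c = as_array(C0)
    if p.shape != c.shape:
        raise ValueError(f"shape mismatch: phi {p.shape} vs C0 {c.shape}")
    ps = np.clip(p, -1.0, 1.0)
    B = eps * c * (ps * ps - 1.0)
    if cutoff > 0.0:
        B[(1.0 - ps * ps) <= cutoff] = 0.0
    return B


def rhs(
    phi: ScalarField | np.ndarray,
    C0: ScalarField | np.ndarray,
    params: ModelParams = ModelParams(),
) -> np.ndarray:
    """Right-hand side of the governing equation (vectorized)."""
    p = as_array(phi)
    c = as_array(C0)
    eps2 = params.eps**2
    mu = -p + p**3 - eps2 * laplacian_5pt(p)
    B = interaction_term(p, c, params.eps, cutoff=params.interface_cutoff)
    env = 2.0 * p * params.eps * c * B - eps2 * laplacian_5pt(B)
    if params.env_grouping == "conserved":
        out = params.M * laplacian_5pt(mu + env)
    else:
        out = params.M * laplacian_5pt(mu) + env
    if not np.all(np.isfinite(out)):
        raise InstabilityError(-1, float(np.nanmax(np.abs(p))))
    return out


def apply_reservoir(
    phi: ScalarField | np.ndarray, res: ReservoirSpec | None
) -> np.ndarray:
    """Pin phi to the reservoir value on masked sites (copy-on-write)."""
    a = as_array(phi)
    if res is None or not res.mask.any():
        return a
    if res.mask.shape != a.shape:
        raise ValueError("reservoir mask shape does not match phi")
    out = a.copy()
    out[res.mask] = res.value
    return out


def step(
    state: PhaseState,
    env: EnvironmentLandscape,
    params: ModelParams,
    res: ReservoirSpec | None = None,
) -> PhaseState:
    """One explicit Euler step followed by reservoir pinning."""
    p = state.phi.values
    new = p + params.dt * rhs(p, env.C0.values, params)
    m = float(np.max(np.abs(new)))
    if not np.isfinite(m) or m > 1.0 + params.overshoot_tol:
        raise InstabilityError(state.step_index, m)
    new = apply_reservoir(new, res)
    return PhaseState(
        ScalarField(new, "phi"),
        t_insilico=state.t_insilico + params.dt,
        step_index=state.step_index + 1,
    )


def free_energy(
    phi: ScalarField | np.ndarray, eps: float = 1.0, dx: float = 1.0
) -> float:
    """Discrete double-well free energy with a square-gradient penalty."""
    p = as_array(phi)
    pad = np.pad(p, 1, mode="edge")
    gx = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / (2.0 * dx)
    gy = (pad[1:-1, 2:] - pad[1:-1, :-2]) / (2.0 * dx)
    dens = -0.5 * p * p + 0.25 * p**4 + 0.5 * eps**2 * (gx * gx + gy * gy)
    return float(dens.sum() * dx * dx)


def tanh_interface(coord: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Equilibrium 1-D interface profile: tanh(coord / (sqrt(2) * eps))."""
    return np.tanh(coord / (np.sqrt(2.0) * eps))


# ---------------------------------------------------------------------------
# Trajectory containers and the simulation driver
# ---------------------------------------------------------------------------


@dataclass
class Snapshot:
    """State captured at one scheduled time."""

    t_h: float
    t_insilico: float
    step_index: int
    phi: np.ndarray
    sum_phi: float
    hydrogel: np.ndarray | None = None  # set when degradation has mutated the ECM


@dataclass
class Trajectory:
    """Time-ordered snapshots plus the (possibly mutating) environment."""

    grid: GridSpec
    snapshots: list[Snapshot] = field(default_factory=list)
    env_initial: EnvironmentLandscape | None = None
    events: list[dict] = field(default_factory=list)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([s.t_h for s in self.snapshots])

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    def hydrogel_at(self, k: int) -> np.ndarray:
        """Hydrogel field in effect at snapshot k (latest mutation, else initial)."""
        for s in reversed(self.snapshots[: k + 1]):
            if s.hydrogel is not None:
                return s.hydrogel
        return self.env_initial.hydrogel.values


def _advance_numpy(phi, C0, res, params, nsteps, start_step):
    for s in range(nsteps):
        new = phi + params.dt * rhs(phi, C0, params)
        m = float(np.max(np.abs(new)))
        if not np.isfinite(m) or m > 1.0 + params.overshoot_tol:
            raise InstabilityError(start_step + s, m)
        if res is not None and res.mask.any():
            new[res.mask] = res.value
        phi = new
    return phi


def _advance_fast(phi, C0, res, params, nsteps, start_step):
    from ._kernels import GROUP_ADDITIVE, GROUP_CONSERVED, advance

    mask = (
        res.mask
        if res is not None and res.mask.any()
        else np.zeros(phi.shape, dtype=bool)
    )
    value = res.value if res is not None and res.mask.any() else 0.0
    grouping = (
        GROUP_CONSERVED if params.env_grouping == "conserved" else GROUP_ADDITIVE
    )
    bad = advance(
        phi,
        np.ascontiguousarray(C0),
        mask,
        value,
        params.M,
        params.eps,
        params.dt,
        nsteps,
        grouping,
        params.overshoot_tol,
        params.interface_cutoff,
    )
    if bad >= 0:
        raise InstabilityError(start_step + bad, float(np.nanmax(np.abs(phi))))
    return phi


def run_simulation(
    env: EnvironmentLandscape,
    params: ModelParams,
    grid: GridSpec,
    res: ReservoirSpec | None,
    initial: PhaseState,
    schedule_hours,
    degradation=None,
    engine: str = "fast",
    progress: bool = False,
) -> Trajectory:
    """Integrate the dynamics, capturing snapshots at scheduled hours.

    ``degradation`` is an optional :class:`~sproutfield.degradation.DegradationParams`;
    when given, a sensing/degradation event mutates the environment every
    ``cadence_steps`` and is logged in ``Trajectory.events``.  The trajectory
    always contains the initial state at its starting time.  ``engine`` is
    ``"fast"`` (numba) or ``"numpy"`` (reference implementation).
    """
    if initial.phi.shape != grid.shape:
        raise ValueError("initial phi shape does not match grid")
    if env.C0.shape != grid.shape:
        raise ValueError("environment shape does not match grid")
    if engine not in ("fast", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")
    advance = _advance_fast if engine == "fast" else _advance_numpy

    env = env.copy() if degradation is not None else env
    schedule = sorted(float(t) for t in schedule_hours)
    snap_steps = []
    for t_h in schedule:
        target = grid.hours_to_insilico(t_h)
        k = int(round((target - initial.t_insilico) / params.dt))
        if k < 0:
            raise ValueError(f"scheduled time {t_h} h precedes the initial state")
        snap_steps.append(k)

    traj = Trajectory(grid=grid, env_initial=env.copy() if degradation is not None else env)
    phi = initial.phi.values.copy()
    if res is not None and res.mask.any():
        phi[res.mask] = res.value
    state_step = 0
    t0 = initial.t_insilico

    def record(k: int, mutated: bool) -> None:
        t_ins = t0 + k * params.dt
        traj.snapshots.append(
            Snapshot(
                t_h=grid.insilico_to_hours(t_ins),
                t_insilico=t_ins,
                step_index=initial.step_index + k,
                phi=phi.copy(),
                sum_phi=float(phi.sum()),
                hydrogel=env.hydrogel.values.copy() if mutated else None,
            )
        )

    record(0, False)
    if not snap_steps:
        return traj

    total = max(snap_steps)
    cadence = None
    if degradation is not None:
        cadence = degradation.resolve_cadence_steps(grid, params.dt)

    breakpoints = set(snap_steps)
    if cadence:
        breakpoints.update(range(cadence, total + 1, cadence))
    breakpoints = sorted(b for b in breakpoints if 0 < b <= total)

    from .degradation import degradation_event  # local import: avoids a cycle

    mutated_since_snap = False
    for b in breakpoints:
        n = b - state_step
        if n > 0:
            phi = advance(phi, env.C0.values, res, params, n, state_step)
            state_step = b
        if cadence and b % cadence == 0:
            st = PhaseState(ScalarField(phi, "phi"), t0 + b * params.dt, b)
            env, decision = degradation_event(st, env, degradation)
            mutated_since_snap = True
            traj.events.append(
                {
                    "time_h": grid.insilico_to_hours(t0 + b * params.dt),
                    "tip_x": decision.tip.x,
                    "tip_y": decision.tip.y,
                    "heading_x": decision.chosen_heading[0],
                    "heading_y": decision.chosen_heading[1],
                    "target_x": decision.target_center[0],
                    "target_y": decision.target_center[1],
                    "hydrogel_mass": float(env.hydrogel.values.sum()),
                }
            )
        if b in set(snap_steps):
            record(b, degradation is not None and mutated_since_snap)
            mutated_since_snap = False
        if progress:
            print(
                f"step {b}/{total}  t={grid.insilico_to_hours(t0 + b * params.dt):.2f} h"
                f"  max|phi|={np.abs(phi).max():.3f}"
            )
    return traj
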