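"""Tip-cell environment sensing and MMP-mediated matrix degradation.

The leading (tip) cell of a sprout probes the hydrogel a couple of cell
diameters ahead of itself, picks the heading of least matrix density among
candidates oriented toward increasing chemoattractant, and releases matrix
metalloproteinases there.  The enzymes erode the hydrogel with a Gaussian
footprint, after which the composite environment map is recomposed.  All
tie-breaks are deterministic so runs reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_env import EnvironmentLandscape, GridSpec, ScalarField, as_array

__all__ = [
    "DegradationParams",
    "TipPosition",
    "SenseDecision",
    "locate_tip",
    "sense_environment",
    "deposit_mmp",
    "degradation_event",
]

#: Default simulated time between sensing/degradation events (hours).
DEFAULT_EVENT_PERIOD_H = 0.275


@dataclass(frozen=True)
class DegradationParams:
    """Sensing geometry and degradative strength of the tip cell.

    ``sensing_radius_px`` is the look-ahead distance (10 px here is about
    two cell diameters, 40 um at the default calibration).  ``power`` scales
    the peak hydrogel removal per event; ``sigma_px`` is the MMP Gaussian
    footprint.  ``cadence_steps`` is the number of Euler steps between
    events; ``None`` derives it from :data:`DEFAULT_EVENT_PERIOD_H`.
    """

    sensing_radius_px: float = 10.0
    power: float = 0.2
    sigma_px: float = 5.0
    cadence_steps: int | None = None
    heading_halfangle_deg: float = 60.0
    n_headings: int = 9
    #: scores within this of the minimum count as ties (resolved toward
    #: straight chemoattractant ascent), preventing sideways drift on
    #: near-uniform matrix
    score_tie_tol: float = 0.02
    advance_axis: int = 1
    advance_direction: int = -1

    def __post_init__(self) -> None:
        if self.sensing_radius_px < 1:
            raise ValueError("sensing_radius_px must be >= 1")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.cadence_steps is not None and self.cadence_steps < 1:
            raise ValueError("cadence_steps must be >= 1")
        if self.n_headings < 1:
            raise ValueError("n_headings must be >= 1")

    def resolve_cadence_steps(self, grid: GridSpec, dt: float) -> int:
        if self.cadence_steps is not None:
            return self.cadence_steps
        return max(1, int(round(DEFAULT_EVENT_PERIOD_H / grid.time_unit_h / dt)))


@dataclass(frozen=True)
class TipPosition:
    """Most advanced cell-phase site along the advancement direction."""

    x: int
    y: int
    t_insilico: float = 0.0


@dataclass(frozen=True)
class SenseDecision:
    """Outcome of one sensing event."""

    tip: TipPosition
    chosen_heading: tuple[float, float]
    target_center: tuple[int, int]
    window_scores: tuple[float, ...]


def locate_tip(
    phi: ScalarField | np.ndarray,
    axis: int = 1,
    direction: int = -1,
    t_insilico: float = 0.0,
) -> TipPosition:
    """Find the most advanced cell site (phi >= 0) along the advancement axis.

    Ties along the advancement coordinate are broken by proximity of the
    transverse coordinate to the cell-mask centroid, then by the smallest
    transverse index.
    """
    p = as_array(phi)
    cells = p >= 0.0
    if not cells.any():
        raise ValueError("no cell sites (phi >= 0) present")
    xs, ys = np.nonzero(cells)
    adv = ys if axis == 1 else xs
    trans = xs if axis == 1 else ys
    extreme = adv.min() if direction == -1 else adv.max()
    at_front = adv == extreme
    centroid_trans = float(trans.mean())
    cand = trans[at_front]
    dist = np.abs(cand - centroid_trans)
    best = cand[np.lexsort((cand, dist))][0]
    if axis == 1:
        return TipPosition(x=int(best), y=int(extreme), t_insilico=t_insilico)
    return TipPosition(x=int(extreme), y=int(best), t_insilico=t_insilico)


def _ascent_direction(env: EnvironmentLandscape, tip: TipPosition, params) -> np.ndarray:
    """Local chemoattractant ascent direction at the tip (unit vector)."""
    gx, gy = np.gradient(env.nu_c.values)
    g = np.array([gx[tip.x, tip.y], gy[tip.x, tip.y]])
    norm = float(np.hypot(*g))
    if norm < 1e-12:
        fallback = np.zeros(2)
        fallback[params.advance_axis] = params.advance_direction
        return fallback
    return g / norm


def _disc_mean(h: np.ndarray, cx: float, cy: float, radius: float) -> float | None:
    """Mean of h over the in-grid part of a disc; None if fully outside."""
    nx, ny = h.shape
    i0, i1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius)) + 1
    j0, j1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius)) + 1
    i0, j0 = max(i0, 0), max(j0, 0)
    i1, j1 = min(i1, nx), min(j1, ny)
    if i0 >= i1 or j0 >= j1:
        return None
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    mask = (ii - cx) ** 2 + (jj - cy) ** 2 <= radius**2
    if not mask.any():
        return None
    return float(h[i0:i1, j0:j1][mask].mean())


def sense_environment(
    env: EnvironmentLandscape, tip: TipPosition, params: DegradationParams
) -> SenseDecision:
    """Score candidate headings and choose the path of lowest matrix density.

    Candidates span ``+-heading_halfangle_deg`` about the local
    chemoattractant ascent direction; each is scored by the mean hydrogel
    density over a look-ahead disc of radius ``sigma_px`` centred
    ``sensing_radius_px`` away.  The minimum-score heading wins, ties going
    to the heading closest to straight ascent.
    """
    h = env.hydrogel.values
    nx, ny = h.shape
    ascent = _ascent_direction(env, tip, params)
    base = np.arctan2(ascent[1], ascent[0])
    half = np.deg2rad(params.heading_halfangle_deg)
    if params.n_headings == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-half, half, params.n_headings)
    # order by |offset| so the argmin tie-break prefers straight ascent
    order = np.argsort(np.abs(offsets), kind="stable")
    offsets = offsets[order]

    scores = []
    headings = []
    centers = []
    for off in offsets:
        ang = base + off
        ux, uy = np.cos(ang), np.sin(ang)
        cx = tip.x + params.sensing_radius_px * ux
        cy = tip.y + params.sensing_radius_px * uy
        score = _disc_mean(h, cx, cy, params.sigma_px)
        if score is None:
            continue
        scores.append(score)
        headings.append((float(ux), float(uy)))
        centers.append((cx, cy))
    if not scores:
        # tip at the advancement edge: every look-ahead disc is outside the
        # grid; fall back to straight ascent with the centre clamped inside
        ux, uy = float(ascent[0]), float(ascent[1])
        cx = tip.x + params.sensing_radius_px * ux
        cy = tip.y + params.sensing_radius_px * uy
        target = (
            int(np.clip(round(cx), 0, nx - 1)),
            int(np.clip(round(cy), 0, ny - 1)),
        )
        return SenseDecision(
            tip=tip, chosen_heading=(ux, uy), target_center=target, window_scores=()
        )
    # candidates are ordered by |offset|: the first one within the tie
    # tolerance of the minimum is the most ascent-aligned near-minimum
    lo = min(scores)
    best = next(i for i, s in enumerate(scores) if s <= lo + params.score_tie_tol)
    cx, cy = centers[best]
    target = (
        int(np.clip(round(cx), 0, nx - 1)),
        int(np.clip(round(cy), 0, ny - 1)),
    )
    return SenseDecision(
        tip=tip,
        chosen_heading=headings[best],
        target_center=target,
        window_scores=tuple(scores),
    )


def deposit_mmp(
    h: ScalarField | np.ndarray,
    center: tuple[float, float],
    params: DegradationParams,
) -> ScalarField:
    """Erode the hydrogel with a unit-peak Gaussian footprint, clamped at 0.

    The footprint is truncated beyond 4 sigma, so the field is untouched
    far from the deposition centre.
    """
    vals = as_array(h).copy()
    nx, ny = vals.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"deposition centre {center} outside the grid")
    if params.power == 0.0:
        return ScalarField(vals, "hydrogel_density")
    reach = 4.0 * params.sigma_px
    i0, i1 = max(int(np.floor(cx - reach)), 0), min(int(np.ceil(cx + reach)) + 1, nx)
    j0, j1 = max(int(np.floor(cy - reach)), 0), min(int(np.ceil(cy + reach)) + 1, ny)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    r2 = (ii - cx) ** 2 + (jj - cy) ** 2
    g = np.exp(-r2 / (2.0 * params.sigma_px**2))
    g[r2 > reach**2] = 0.0
    vals[i0:i1, j0:j1] = np.maximum(vals[i0:i1, j0:j1] - params.power * g, 0.0)
    return ScalarField(vals, "hydrogel_density")


def degradation_event(
    state, env: EnvironmentLandscape, params: DegradationParams
) -> tuple[EnvironmentLandscape, SenseDecision]:
    """One sensing + degradation cycle: locate tip, sense, erode, recompose.

    Returns the mutated environment (same object, recomposed in place) and
    the sensing decision.  Total hydrogel mass never increases.
    """
    tip = locate_tip(
        state.phi,
        axis=params.advance_axis,
        direction=params.advance_direction,
        t_insilico=state.t_insilico,
    )
    decision = sense_environment(env, tip, params)
    env.hydrogel = deposit_mmp(env.hydrogel, decision.target_center, params)
    env.recompose()
    return env, decision
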