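"""Quantitative outputs: tip tracking, velocities, volume flux, pore sizes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_env import GridSpec, ScalarField, as_array
from .degradation import locate_tip

__all__ = [
    "TipTrack",
    "FluxResult",
    "tip_track",
    "mean_tip_velocity",
    "migration_distance",
    "first_crossing_time",
    "volume_flux",
    "local_thickness",
    "measure_mean_pore_size",
    "tortuosity",
]


@dataclass
class TipTrack:
    """Tip position per snapshot, times in hours, coordinates in pixels."""

    times_h: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.times_h) == len(self.x_px) == len(self.y_px)):
            raise ValueError("track columns must have equal length")
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_h)

    def position_at(self, t_h: float) -> tuple[float, float]:
        """Linearly interpolated (x, y) at time t_h (must lie in the span).

        Times within a relative 1e-4 of the endpoints are clamped, absorbing
        the step-quantization of snapshot schedules.
        """
        t = self.times_h
        tol = 1e-4 * max(1.0, abs(t_h))
        if t[0] - tol <= t_h < t[0]:
            t_h = t[0]
        elif t[-1] < t_h <= t[-1] + tol:
            t_h = t[-1]
        if not (t[0] <= t_h <= t[-1]):
            raise ValueError(f"time {t_h} h outside the track span [{t[0]}, {t[-1]}]")
        return (
            float(np.interp(t_h, t, self.x_px)),
            float(np.interp(t_h, t, self.y_px)),
        )

    def to_dataframe(self, grid: GridSpec | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_h": self.times_h, "x_px": self.x_px, "y_px": self.y_px}
        )
        if grid is not None:
            df["y_um"] = df["y_px"] * grid.dx_um
        return df


@dataclass(frozen=True)
class FluxResult:
    """Net phase volume change per hour between two snapshots.

    ``raw_rate`` is d(sum phi)/dt in h^-1; ``fraction_rate`` divides by
    2 * N_sites so that complete conversion of the whole domain over the
    window corresponds to 1/(t - t0).
    """

    t0_h: float
    t_h: float
    raw_rate: float
    fraction_rate: float


def tip_track(traj, axis: int = 1, direction: int = -1) -> TipTrack:
    """Per-snapshot tip positions of a trajectory."""
    if not traj.snapshots:
        raise ValueError("trajectory holds no snapshots")
    times, xs, ys = [], [], []
    for s in traj.snapshots:
        tp = locate_tip(s.phi, axis=axis, direction=direction)
        times.append(s.t_h)
        xs.append(tp.x)
        ys.append(tp.y)
    return TipTrack(np.array(times), np.array(xs), np.array(ys))


def mean_tip_velocity(
    track: TipTrack, t_start_h: float, t_end_h: float, grid: GridSpec
) -> float:
    """Signed mean tip velocity along y in um/h over [t_start, t_end].

    Advancement toward decreasing y yields a negative velocity.
    """
    if t_end_h <= t_start_h:
        raise ValueError("t_end must exceed t_start")
    _, y0 = track.position_at(t_start_h)
    _, y1 = track.position_at(t_end_h)
    return (y1 - y0) * grid.dx_um / (t_end_h - t_start_h)


def migration_distance(track: TipTrack, t_hours: float, grid: GridSpec) -> float:
    """Absolute tip displacement along y from the start of the track, in um."""
    _, y_t = track.position_at(t_hours)
    return abs(y_t - track.y_px[0]) * grid.dx_um


def first_crossing_time(track: TipTrack, y_level: float, direction: int = -1) -> float:
    """First time (h) the tip reaches y_level moving in ``direction``.

    Linear interpolation between snapshots; raises if the level is never
    reached.
    """
    y = track.y_px
    t = track.times_h
    reached = y <= y_level if direction == -1 else y >= y_level
    if not reached.any():
        raise ValueError(f"tip never reaches y = {y_level}")
    k = int(np.argmax(reached))
    if k == 0:
        return float(t[0])
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t[k])
    frac = (y_level - y0) / (y1 - y0)
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def _snapshot_at(traj, t_h: float):
    times = traj.times_h
    k = int(np.argmin(np.abs(times - t_h)))
    if abs(times[k] - t_h) > 1e-6 + 1e-3 * max(1.0, abs(t_h)):
        raise ValueError(f"no snapshot near t = {t_h} h (have {times})")
    return traj.snapshots[k]


def volume_flux(traj, t0_h: float, t_h: float) -> FluxResult:
    """Net phase volume change rate between the snapshots at t0_h and t_h."""
    s0 = _snapshot_at(traj, t0_h)
    s1 = _snapshot_at(traj, t_h)
    if s1.t_h <= s0.t_h:
        raise ValueError("t_h must exceed t0_h")
    dt = s1.t_h - s0.t_h
    raw = (s1.sum_phi - s0.sum_phi) / dt
    n_sites = s1.phi.size
    return FluxResult(
        t0_h=s0.t_h, t_h=s1.t_h, raw_rate=raw, fraction_rate=raw / (2.0 * n_sites)
    )


def local_thickness(pore_mask: np.ndarray) -> np.ndarray:
    """Largest inscribed-disc diameter covering each pore site (pixels).

    Implements the standard local-thickness morphometric: the Euclidean
    distance transform gives the largest disc centred at each pore site;
    discs are then painted largest-first so every covered site records the
    diameter of the biggest disc containing it.
    """
    pore = np.asarray(pore_mask, dtype=bool)
    thickness = np.zeros(pore.shape, dtype=float)
    if not pore.any():
        return thickness
    edt = ndimage.distance_transform_edt(pore)
    xs, ys = np.nonzero(pore)
    radii = edt[xs, ys]
    order = np.argsort(radii)[::-1]
    nx, ny = pore.shape
    for k in order:
        cx, cy, r = xs[k], ys[k], radii[k]
        d = 2.0 * r
        i0, i1 = max(int(cx - r), 0), min(int(cx + r) + 1, nx)
        j0, j1 = max(int(cy - r), 0), min(int(cy + r) + 1, ny)
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        disc = ((ii - cx) ** 2 + (jj - cy) ** 2 <= r * r) & pore[i0:i1, j0:j1]
        sub = thickness[i0:i1, j0:j1]
        np.maximum(sub, np.where(disc, d, 0.0), out=sub)
    return thickness


def measure_mean_pore_size(
    h: ScalarField | np.ndarray,
    pore_threshold: float = 0.5,
    grid: GridSpec | None = None,
) -> float:
    """Mean pore diameter (um) of the binarized hydrogel by local thickness.

    Pore space is ``h < pore_threshold``.  The estimate is the mean over
    pore sites of the largest inscribed-disc diameter covering each site,
    scaled by the pixel size.
    """
    vals = as_array(h)
    dx_um = grid.dx_um if grid is not None else 1.0
    pore = vals < pore_threshold
    if not pore.any():
        raise ValueError("no pore sites below the threshold")
    if pore.all():
        warnings.warn("field is all pore; returning the domain-scale bound")
        return float(min(vals.shape)) * dx_um
    thick = local_thickness(pore)
    return float(thick[pore].mean()) * dx_um


def tortuosity(track: TipTrack) -> float:
    """Path length over net displacement of the tip trajectory."""
    dx = np.diff(track.x_px)
    dy = np.diff(track.y_px)
    path = float(np.sum(np.hypot(dx, dy)))
    net = float(
        np.hypot(track.x_px[-1] - track.x_px[0], track.y_px[-1] - track.y_px[0])
    )
    if net == 0.0:
        return np.inf if path > 0 else 1.0
    return path / net
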