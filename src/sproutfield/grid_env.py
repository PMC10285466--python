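"""Simulation grid and composite cell-environment landscape.

The environment a migrating cell collection feels is a single scalar map
``C0`` composed of a chemoattractant distribution ``nu_c`` and the hydrogel
(extracellular-matrix) density ``h``::

    C0 = max(nu_c - gamma * h, floor)

Dense hydrogel suppresses ``C0`` toward the immobile band; open pores carry
the full chemoattractant level.  Sites are classified into three bands:

====================  ==============================
``C0 < 0.1``          hydrogel (immobile)
``0.1 <= C0 < 0.2``   hydrogel-pore interface
``0.2 <= C0 <= 0.5``  pore with chemotactic factors
====================  ==============================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "GridSpec",
    "ScalarField",
    "ChemotacticSpec",
    "EcmGenSpec",
    "PathSpec",
    "EnvironmentLandscape",
    "BAND_HYDROGEL",
    "BAND_INTERFACE",
    "BAND_CHEMO_PORE",
    "make_gradient",
    "load_hydrogel_image",
    "generate_synthetic_ecm",
    "calibrate_correlation_length",
    "carve_open_path",
    "compose_environment",
    "classify_bands",
]

# Band codes (integer labels used in EnvironmentLandscape.bands)
BAND_HYDROGEL = 0
BAND_INTERFACE = 1
BAND_CHEMO_PORE = 2

#: Upper admissible level of the composite environment map.
C0_MAX = 0.5

#: Number of grid points that span one unit of the gradient coordinate.
#: A slope ``alpha`` printed per "y" is applied per 100 grid points, so the
#: default 200-point domain spans exactly two coordinate units and the
#: default linear gradient 0.1*y + 0.3 covers [0.3, 0.5].
GRADIENT_UNIT_PX = 100.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry and physical calibration of the square simulation lattice.

    One lattice spacing is ``dx_um`` micrometres and one in-silico time unit
    is ``time_unit_h`` hours; an Euler step advances ``dt`` in-silico units.
    """

    nx: int = 200
    ny: int = 200
    dx_um: float = 3.85
    time_unit_h: float = 2.75e-3
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.dx_um <= 0 or self.time_unit_h <= 0 or self.dt <= 0:
            raise ValueError("dx_um, time_unit_h and dt must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def step_hours(self) -> float:
        """Physical duration of one Euler step."""
        return self.dt * self.time_unit_h

    def hours_to_insilico(self, t_h: float) -> float:
        return t_h / self.time_unit_h

    def insilico_to_hours(self, t: float) -> float:
        return t * self.time_unit_h


@dataclass
class ScalarField:
    """A 2-D lattice of real values tagged with its role in the model."""

    values: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarField requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in ScalarField role={self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.role)


def as_array(f) -> np.ndarray:
    """Accept a ScalarField or a bare array and return the ndarray view."""
    if isinstance(f, ScalarField):
        return f.values
    return np.asarray(f, dtype=float)


@dataclass(frozen=True)
class ChemotacticSpec:
    """Chemoattractant profile along the advancement axis.

    ``axis`` is the lattice axis along which cells advance (1 = the second
    array axis, the default).  ``direction`` is the sign of advancement along
    that axis: ``-1`` means cells start at the high-index edge and migrate
    toward index 0, which is the default configuration.  The gradient
    coordinate is the pixel distance from the cell-side edge divided by
    ``GRADIENT_UNIT_PX``.
    """

    profile: str = "linear"  # linear | peaked | uniform | zero
    alpha: float = 0.1
    beta: float = 0.3
    axis: int = 1
    direction: int = -1
    peak_start: float = 0.1
    peak_level: float = 0.5
    peak_pos_px: float = 100.0

    def __post_init__(self) -> None:
        if self.profile not in ("linear", "peaked", "uniform", "zero"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


def _advancement_coordinate(spec: ChemotacticSpec, grid: GridSpec) -> np.ndarray:
    """Pixel distance from the cell-side edge, broadcast to the grid shape."""
    n = grid.shape[spec.axis]
    idx = np.arange(n, dtype=float)
    u = (n - 1) - idx if spec.direction == -1 else idx
    if spec.axis == 1:
        return np.broadcast_to(u[None, :], grid.shape).copy()
    return np.broadcast_to(u[:, None], grid.shape).copy()


def make_gradient(spec: ChemotacticSpec, grid: GridSpec) -> ScalarField:
    """Evaluate a chemoattractant profile on the grid.

    Linear profiles follow ``alpha * u + beta`` with ``u`` the advancement
    coordinate in units of :data:`GRADIENT_UNIT_PX` grid points, clipped to
    ``[0, 0.5]``.  Peaked profiles rise linearly from ``peak_start`` at the
    cell-side edge to ``peak_level`` at ``peak_pos_px`` and then decay
    linearly to zero at the far edge.
    """
    if spec.profile == "zero":
        return ScalarField(np.zeros(grid.shape), "nu_c")
    if spec.profile == "uniform":
        if not 0.0 <= spec.beta <= C0_MAX:
            raise ValueError(f"uniform level {spec.beta} outside [0, {C0_MAX}]")
        return ScalarField(np.full(grid.shape, spec.beta), "nu_c")

    u_px = _advancement_coordinate(spec, grid)
    if spec.profile == "linear":
        if not 0.0 <= spec.beta <= C0_MAX:
            raise ValueError(f"offset beta={spec.beta} outside [0, {C0_MAX}]")
        vals = spec.alpha * (u_px / GRADIENT_UNIT_PX) + spec.beta
        vals = np.clip(vals, 0.0, C0_MAX)
        return ScalarField(vals, "nu_c")

    # peaked
    for name, v in (("peak_start", spec.peak_start), ("peak_level", spec.peak_level)):
        if not 0.0 <= v <= C0_MAX:
            raise ValueError(f"{name}={v} outside [0, {C0_MAX}]")
    n = grid.shape[spec.axis]
    far = float(n - 1)
    pos = float(spec.peak_pos_px)
    if not 0.0 < pos < far:
        raise ValueError("peak position must lie strictly inside the domain")
    rising = spec.peak_start + (spec.peak_level - spec.peak_start) * (u_px / pos)
    decaying = spec.peak_level * (far - u_px) / (far - pos)
    vals = np.where(u_px <= pos, rising, decaying)
    vals = np.clip(vals, 0.0, C0_MAX)
    return ScalarField(vals, "nu_c")


# luminance weights of ITU-R BT.709, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def load_hydrogel_image(path, grid: GridSpec) -> ScalarField:
    """Load a raster image as a normalized hydrogel density field.

    The image is luminance-converted, min-max normalized to [0, 1]
    (1 = densest hydrogel) and resampled to the grid by area averaging.
    A constant (zero dynamic range) input triggers a warning and yields an
    all-zero field.
    """
    img = np.asarray(Image.open(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    elif img.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {img.ndim}")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("hydrogel image has zero dynamic range; returning a constant field")
        return ScalarField(np.zeros(grid.shape), "hydrogel_density")
    img = (img - lo) / (hi - lo)
    # PIL's BOX filter is an exact area average; PIL sizes are (width, height)
    # = (ncols, nrows), and our array axes are (nx, ny) = (rows, cols).
    resized = Image.fromarray(img.astype(np.float32), mode="F").resize(
        (grid.ny, grid.nx), resample=Image.Resampling.BOX
    )
    vals = np.clip(np.asarray(resized, dtype=float), 0.0, 1.0)
    return ScalarField(vals, "hydrogel_density")


@dataclass(frozen=True)
class EcmGenSpec:
    """Parameters of the synthetic porous-hydrogel generator.

    The generator thresholds a Gaussian-smoothed white-noise field at the
    quantile matching ``porosity``; ``correlation_length_px`` sets the pore
    scale and is calibrated (see :func:`calibrate_correlation_length`)
    against the mean inscribed-disc pore diameter.  ``None`` requests
    automatic calibration toward ``target_mean_pore_um``.
    """

    porosity: float = 0.25
    target_mean_pore_um: float = 40.0
    correlation_length_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")
        if self.target_mean_pore_um <= 0:
            raise ValueError("target_mean_pore_um must be positive")
        if self.correlation_length_px is not None and self.correlation_length_px <= 0:
            raise ValueError("correlation_length_px must be positive")


#: Correlation length (px) calibrated so that the default spec (porosity 0.25,
#: below the level-set percolation threshold so pore clusters are finite)
#: yields a 40 um mean pore diameter on the default 200x200 grid at
#: dx = 3.85 um.  Recomputed by ``calibrate_correlation_length``.
DEFAULT_CORRELATION_LENGTH_PX = 3.59


def _smooth_noise(nx: int, ny: int, sigma_px: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nx, ny))
    return ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")


def generate_synthetic_ecm(spec: EcmGenSpec, grid: GridSpec) -> ScalarField:
    """Generate a binary porous hydrogel density field (1 = matrix, 0 = pore).

    Deterministic given the spec and seed.  If ``correlation_length_px`` is
    unset it is calibrated on the fly for the requested target pore size.
    """
    corr = spec.correlation_length_px
    if corr is None:
        if (
            spec.target_mean_pore_um == 40.0
            and spec.porosity == 0.25
            and grid.dx_um == 3.85
            and min(grid.nx, grid.ny) >= 100
        ):
            corr = DEFAULT_CORRELATION_LENGTH_PX  # precalibrated standard spec
        else:
            corr = calibrate_correlation_length(
                spec.target_mean_pore_um, spec.porosity, grid
            )
    f = _smooth_noise(grid.nx, grid.ny, corr, spec.seed)
    thr = np.quantile(f, spec.porosity)
    h = np.where(f < thr, 0.0, 1.0)
    return ScalarField(h, "hydrogel_density")


def calibrate_correlation_length(
    target_mean_pore_um: float,
    porosity: float,
    grid: GridSpec,
    seeds: tuple[int, ...] = (101, 102, 103),
    tol_frac: float = 0.05,
    max_iter: int = 40,
) -> float:
    """Bisect the smoothing scale until the generated mean pore size matches.

    Mean pore size grows monotonically with the correlation length of the
    underlying random field, so bisection on ``correlation_length_px``
    converges.  Raises if the target cannot be bracketed on the grid.
    """
    from .metrics import measure_mean_pore_size

    def measured(corr: float) -> float:
        sizes = []
        for s in seeds:
            f = _smooth_noise(grid.nx, grid.ny, corr, s)
            thr = np.quantile(f, porosity)
            h = np.where(f < thr, 0.0, 1.0)
            sizes.append(measure_mean_pore_size(h, grid=grid))
        return float(np.mean(sizes))

    lo, hi = 0.5, min(grid.nx, grid.ny) / 4.0
    m_lo, m_hi = measured(lo), measured(hi)
    if not (m_lo <= target_mean_pore_um <= m_hi):
        raise ValueError(
            f"cannot reach target pore size {target_mean_pore_um} um on this grid: "
            f"achievable range [{m_lo:.1f}, {m_hi:.1f}] um"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = measured(mid)
        if abs(m - target_mean_pore_um) <= tol_frac * target_mean_pore_um:
            return mid
        if m < target_mean_pore_um:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PathSpec:
    """A carved corridor: a polyline of waypoints swept by a disc."""

    waypoints: tuple[tuple[float, float], ...]
    width_px: float = 10.0

    def __post_init__(self) -> None:
        if len(self.waypoints) == 0:
            raise ValueError("PathSpec requires at least one waypoint")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


def _distance_to_segment(px, py, ax, ay, bx, by):
    """Pointwise distance from grid points (px, py) to segment (a, b)."""
    vx, vy = bx - ax, by - ay
    denom = vx * vx + vy * vy
    if denom == 0.0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def carve_open_path(h: ScalarField | np.ndarray, path: PathSpec) -> ScalarField:
    """Zero the hydrogel density inside a corridor along the waypoint polyline."""
    vals = as_array(h).copy()
    nx, ny = vals.shape
    for x, y in path.waypoints:
        if not (0 <= x < nx and 0 <= y < ny):
            raise ValueError(f"waypoint ({x}, {y}) outside the grid")
    ii, jj = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    half = path.width_px / 2.0
    mask = np.zeros(vals.shape, dtype=bool)
    pts = list(path.waypoints)
    if len(pts) == 1:
        pts = pts * 2
    for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
        mask |= _distance_to_segment(ii, jj, ax, ay, bx, by) <= half
    vals[mask] = 0.0
    return ScalarField(vals, "hydrogel_density")


def classify_bands(C0: ScalarField | np.ndarray) -> np.ndarray:
    """Label every site with its environment band.

    Bands are half-open intervals: ``[0, 0.1)`` hydrogel, ``[0.1, 0.2)``
    interface, ``[0.2, 0.5]`` pore with chemotactic factors.  Values above
    0.5 are rejected; values below 0 (possible only with a negative clamp
    floor) fall in the hydrogel band.
    """
    c = as_array(C0)
    if not np.all(np.isfinite(c)):
        raise ValueError("C0 contains non-finite values")
    if np.any(c > C0_MAX + 1e-12):
        raise ValueError(f"C0 exceeds the admissible maximum {C0_MAX}")
    bands = np.full(c.shape, BAND_HYDROGEL, dtype=np.int8)
    bands[c >= 0.1] = BAND_INTERFACE
    bands[c >= 0.2] = BAND_CHEMO_PORE
    return bands


@dataclass
class EnvironmentLandscape:
    """Hydrogel + chemoattractant composed into the single map ``C0``.

    Mutable only through :meth:`recompose` (used by the degradation rule
    after the hydrogel field has been eroded).
    """

    hydrogel: ScalarField
    nu_c: ScalarField
    gamma: float = 0.5
    floor: float = 0.0
    C0: ScalarField = field(init=False)
    bands: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.hydrogel.shape != self.nu_c.shape:
            raise ValueError(
                f"shape mismatch: hydrogel {self.hydrogel.shape} vs nu_c {self.nu_c.shape}"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        self.recompose()

    @property
    def nu_ecm(self) -> ScalarField:
        return ScalarField(-self.gamma * self.hydrogel.values, "nu_ecm")

    def recompose(self) -> None:
        """Rebuild C0 and the band map from the current hydrogel field."""
        raw = self.nu_c.values - self.gamma * self.hydrogel.values
        c0 = np.maximum(raw, self.floor)
        self.C0 = ScalarField(c0, "C0")
        self.bands = classify_bands(c0)

    def copy(self) -> "EnvironmentLandscape":
        return EnvironmentLandscape(
            self.hydrogel.copy(), self.nu_c.copy(), self.gamma, self.floor
        )


def compose_environment(
    nu_c: ScalarField | np.ndarray,
    h: ScalarField | np.ndarray,
    gamma: float = 0.5,
    floor: float = 0.0,
) -> EnvironmentLandscape:
    """Compose the environment map ``C0 = max(nu_c - gamma*h, floor)``."""
    nu_f = nu_c if isinstance(nu_c, ScalarField) else ScalarField(nu_c, "nu_c")
    h_f = h if isinstance(h, ScalarField) else ScalarField(h, "hydrogel_density")
    return EnvironmentLandscape(h_f, nu_f, gamma=gamma, floor=floor)
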