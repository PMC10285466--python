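"""Raster rendering of simulation states.

Colour conventions: cells red (phi = +1) over blue medium, or a red cell
perimeter only; hydrogel in purple; chemoattractant as a green-to-yellow
background.  Rendering is pure numpy compositing so output bytes are
deterministic for a given input.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .grid_env import EnvironmentLandscape, as_array

__all__ = ["render_snapshot", "save_png"]

_MEDIUM_BLUE = np.array([0.20, 0.30, 0.85])
_CELL_RED = np.array([0.85, 0.10, 0.10])
_HYDROGEL_PURPLE = np.array([0.45, 0.15, 0.55])
_CHEMO_GREEN = np.array([0.10, 0.55, 0.20])
_CHEMO_YELLOW = np.array([0.95, 0.95, 0.30])


def _perimeter(phi: np.ndarray) -> np.ndarray:
    """Sites on the cell side of the phi = 0 contour with a medium neighbour."""
    cells = phi >= 0.0
    pad = np.pad(cells, 1, mode="edge")
    nb_medium = (
        ~pad[2:, 1:-1] | ~pad[:-2, 1:-1] | ~pad[1:-1, 2:] | ~pad[1:-1, :-2]
    )
    return cells & nb_medium


def render_snapshot(
    phi,
    env: EnvironmentLandscape,
    style: str = "fill",
    hydrogel: np.ndarray | None = None,
) -> np.ndarray:
    """Compose an RGB uint8 image of a state over its environment.

    ``style`` is ``"fill"`` (solid red cells on blue medium) or
    ``"perimeter"`` (red phi = 0 contour over the environment).  An eroded
    ``hydrogel`` override can be passed for snapshots after degradation.
    """
    if style not in ("fill", "perimeter"):
        raise ValueError(f"unknown style {style!r}")
    p = as_array(phi)
    h = as_array(hydrogel) if hydrogel is not None else env.hydrogel.values
    nu = env.nu_c.values
    nu_max = nu.max() if nu.max() > 0 else 1.0
    t = (nu / nu_max)[..., None]
    img = _CHEMO_GREEN * (1 - t) + _CHEMO_YELLOW * t
    hh = np.clip(h, 0.0, 1.0)[..., None]
    img = img * (1 - hh) + _HYDROGEL_PURPLE * hh
    if style == "fill":
        cells = p >= 0.0
        img[cells] = _CELL_RED
        img[~cells] = img[~cells] * 0.5 + _MEDIUM_BLUE * 0.5
    else:
        img[_perimeter(p)] = _CELL_RED
    # array axes are (x, y); display with y vertical, advancement downward
    return (np.clip(img.transpose(1, 0, 2), 0, 1) * 255).astype(np.uint8)


def save_png(image: np.ndarray, path) -> None:
    iio.imwrite(path, image)
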