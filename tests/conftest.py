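import numpy as np
import pytest

from sproutfield.grid_env import GridSpec


@pytest.fixture
def grid16():
    return GridSpec(nx=16, ny=16)


@pytest.fixture
def grid32():
    return GridSpec(nx=32, ny=32)


@pytest.fixture
def default_grid():
    return GridSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def naive_rhs(phi, C0, M=1.0, eps=1.0, grouping="additive", cutoff=1e-3):
    """Independent nested-loop evaluation of the governing equation.

    Deliberately written with explicit index loops (no vectorization, no
    shared helpers) as an oracle for the solver implementation.  Includes
    the same bulk saturation/gating of the interaction term as the solver.
    """
    nx, ny = phi.shape

    def lap(f):
        out = np.zeros_like(f)
        for i in range(nx):
            for j in range(ny):
                im = i - 1 if i - 1 >= 0 else 0
                ip = i + 1 if i + 1 <= nx - 1 else nx - 1
                jm = j - 1 if j - 1 >= 0 else 0
                jp = j + 1 if j + 1 <= ny - 1 else ny - 1
                out[i, j] = f[ip, j] + f[im, j] + f[i, jp] + f[i, jm] - 4.0 * f[i, j]
        return out

    B = np.zeros_like(phi)
    mu = np.zeros_like(phi)
    lap_phi = lap(phi)
    for i in range(nx):
        for j in range(ny):
            ps = min(max(phi[i, j], -1.0), 1.0)
            if 1.0 - ps * ps > cutoff:
                B[i, j] = eps * C0[i, j] * (ps * ps - 1.0)
            else:
                B[i, j] = 0.0
            mu[i, j] = -phi[i, j] + phi[i, j] ** 3 - eps**2 * lap_phi[i, j]
    lap_B = lap(B)
    env = np.zeros_like(phi)
    for i in range(nx):
        for j in range(ny):
            env[i, j] = (
                2.0 * phi[i, j] * eps * C0[i, j] * B[i, j] - eps**2 * lap_B[i, j]
            )
    if grouping == "conserved":
        return M * lap(mu + env)
    return M * lap(mu) + env
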