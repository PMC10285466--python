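import numpy as np
import pytest

from conftest import naive_rhs
from sproutfield.grid_env import GridSpec, ScalarField, compose_environment
from sproutfield.solver import (
    InstabilityError,
    ModelParams,
    PhaseState,
    ReservoirSpec,
    apply_reservoir,
    free_energy,
    interaction_term,
    laplacian_5pt,
    rhs,
    run_simulation,
    stability_dt_limit,
    step,
    tanh_interface,
    _advance_fast,
    _advance_numpy,
)


class TestLaplacian:
    def test_constant_annihilated(self):
        f = np.full((12, 12), 3.7)
        assert np.all(laplacian_5pt(f) == 0.0)

    def test_quadratic_exact_interior(self):
        i, j = np.meshgrid(np.arange(16.0), np.arange(16.0), indexing="ij")
        lap = laplacian_5pt(i**2 + j**2)
        assert np.allclose(lap[1:-1, 1:-1], 4.0)

    def test_unit_impulse_stencil(self):
        f = np.zeros((9, 9))
        f[4, 4] = 1.0
        lap = laplacian_5pt(f)
        assert lap[4, 4] == -4.0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert lap[4 + di, 4 + dj] == 1.0
        lap[4, 4] = lap[3, 4] = lap[5, 4] = lap[4, 3] = lap[4, 5] = 0.0
        assert np.all(lap == 0.0)

    def test_dx_scaling(self):
        f = np.random.default_rng(0).normal(size=(8, 8))
        assert np.allclose(laplacian_5pt(f, dx=2.0), laplacian_5pt(f) / 4.0)


class TestInteractionTerm:
    def test_vanishes_in_bulk(self, rng):
        C0 = rng.uniform(0, 0.5, (10, 10))
        for bulk in (1.0, -1.0):
            assert np.all(interaction_term(np.full((10, 10), bulk), C0) == 0.0)

    def test_direct_substitution(self):
        out = interaction_term(np.zeros((4, 4)), np.full((4, 4), 0.5), eps=1.0)
        assert np.allclose(out, -0.5)

    def test_sign_property(self, rng):
        phi = rng.uniform(-1, 1, (20, 20))
        C0 = rng.uniform(0, 0.5, (20, 20))
        assert np.all(interaction_term(phi, C0) <= 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            interaction_term(np.zeros((4, 4)), np.zeros((5, 5)))


class TestRhs:
    @pytest.mark.parametrize("grouping", ["additive", "conserved"])
    def test_oracle_equivalence(self, grouping, rng):
        params = ModelParams(env_grouping=grouping)
        for _ in range(10):
            phi = rng.uniform(-1, 1, (16, 16))
            C0 = rng.uniform(0, 0.5, (16, 16))
            got = rhs(phi, C0, params)
            want = naive_rhs(phi, C0, grouping=grouping)
            assert np.max(np.abs(got - want)) <= 1e-12

    @pytest.mark.parametrize("bulk", [1.0, -1.0])
    @pytest.mark.parametrize("c0", [0.0, 0.3, 0.5])
    def test_homogeneous_bulk_stationary(self, bulk, c0):
        phi = np.full((12, 12), bulk)
        C0 = np.full((12, 12), c0)
        assert np.all(rhs(phi, C0) == 0.0)

    def test_kink_near_equilibrium(self):
        # 1-D tanh interface is the continuum equilibrium of the pure
        # double-well dynamics; the discrete residual is O((dx/eps)^2), so
        # use eps = 2 px to resolve the profile.
        eps = 2.0
        y = np.arange(64.0) - 31.5
        phi = np.broadcast_to(tanh_interface(y, eps)[None, :], (4, 64)).copy()
        params = ModelParams(eps=eps, dt=5e-3)
        out = rhs(phi, np.zeros_like(phi), params)
        assert np.max(np.abs(out)) < 0.02
        # relaxing to the discrete equilibrium drives the residual to ~0
        relaxed = _advance_fast(phi.copy(), np.zeros_like(phi), None, params, 20_000, 0)
        assert np.max(np.abs(rhs(relaxed, np.zeros_like(phi), params))) < 1e-4

    def test_nonfinite_aborts(self):
        phi = np.zeros((8, 8))
        phi[4, 4] = np.inf
        with pytest.raises(InstabilityError):
            rhs(phi, np.zeros_like(phi))


class TestReservoirAndStep:
    def test_empty_mask_identity(self, rng):
        phi = rng.normal(size=(8, 8))
        out = apply_reservoir(phi, ReservoirSpec(np.zeros((8, 8), bool), 1.0))
        assert np.array_equal(out, phi)

    def test_boundary_mask_pins_edges(self, grid16):
        mask = np.zeros(grid16.shape, bool)
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
        env = compose_environment(np.zeros(grid16.shape), np.zeros(grid16.shape))
        state = PhaseState(ScalarField(np.full(grid16.shape, -1.0), "phi"))
        params = ModelParams()
        res = ReservoirSpec(mask, 1.0)
        for _ in range(3):
            state = step(state, env, params, res)
        assert np.all(state.phi.values[mask] == 1.0)

    def test_interior_sphere_mask(self, grid16):
        ii, jj = np.meshgrid(np.arange(16.0), np.arange(16.0), indexing="ij")
        mask = np.hypot(ii - 8, jj - 8) <= 3
        env = compose_environment(np.zeros(grid16.shape), np.zeros(grid16.shape))
        state = PhaseState(ScalarField(np.full(grid16.shape, -1.0), "phi"))
        state = step(state, env, ModelParams(), ReservoirSpec(mask, 1.0))
        assert np.all(state.phi.values[mask] == 1.0)
        assert np.all(state.phi.values[~mask] < 0.0)

    def test_small_dt_limit(self, rng, grid16):
        phi0 = rng.uniform(-0.5, 0.5, grid16.shape)
        env = compose_environment(
            rng.uniform(0, 0.5, grid16.shape), np.zeros(grid16.shape)
        )
        state = PhaseState(ScalarField(phi0, "phi"))
        out = step(state, env, ModelParams(dt=1e-12), None)
        assert np.max(np.abs(out.phi.values - phi0)) < 1e-9
        assert out.step_index == 1

    def test_overshoot_aborts(self):
        phi = np.full((8, 8), 1.25)
        phi[4, 4] = 1.3
        env = compose_environment(np.full((8, 8), 0.5), np.zeros((8, 8)))
        with pytest.raises(InstabilityError):
            step(PhaseState(ScalarField(phi, "phi")), env, ModelParams(), None)

    def test_stability_guard_rejects_large_dt(self):
        limit = stability_dt_limit()
        with pytest.raises(ValueError):
            ModelParams(dt=limit * 1.5)
        ModelParams(dt=limit)  # boundary accepted

    def test_clock_advances(self, grid16):
        env = compose_environment(np.zeros(grid16.shape), np.zeros(grid16.shape))
        state = PhaseState(ScalarField(np.zeros(grid16.shape), "phi"))
        params = ModelParams(dt=1e-3)
        for _ in range(5):
            state = step(state, env, params, None)
        assert state.step_index == 5
        assert state.t_insilico == pytest.approx(5e-3)


class TestConservationAndEnergy:
    def test_mass_conserved_without_environment(self, rng):
        phi = rng.uniform(-0.6, -0.2, (32, 32))
        C0 = np.zeros_like(phi)
        params = ModelParams(dt=1e-3)
        total0 = phi.sum()
        out = _advance_fast(phi.copy(), C0, None, params, 10_000, 0)
        assert abs(out.sum() - total0) / abs(total0) <= 1e-9

    def test_free_energy_bulk_minimum(self):
        for bulk in (1.0, -1.0):
            phi = np.full((10, 10), bulk)
            assert free_energy(phi) == pytest.approx(-100 / 4.0)
        assert free_energy(np.zeros((10, 10))) == 0.0

    def test_free_energy_nonincreasing(self, rng):
        phi = rng.uniform(-0.5, 0.5, (24, 24))
        C0 = np.zeros_like(phi)
        params = ModelParams(dt=1e-3)
        energies = [free_energy(phi)]
        for _ in range(20):
            phi = _advance_fast(phi, C0, None, params, 50, 0)
            energies.append(free_energy(phi))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-10)

    def test_fast_matches_numpy_engine(self, rng):
        phi = rng.uniform(-0.8, 0.8, (20, 20))
        C0 = rng.uniform(0, 0.5, (20, 20))
        for grouping in ("additive", "conserved"):
            params = ModelParams(dt=5e-3, env_grouping=grouping)
            a = _advance_fast(phi.copy(), C0, None, params, 200, 0)
            b = _advance_numpy(phi.copy(), C0, None, params, 200, 0)
            assert np.max(np.abs(a - b)) < 1e-12


class TestBehavioralInvariants:
    def _corridor_displacement(self, level, units=100):
        from sproutfield.metrics import tip_track
        from sproutfield.scenarios import flat_front_phi

        g = GridSpec(nx=60, ny=120, dt=0.02)
        h = np.ones(g.shape)
        h[25:35, :] = 0.0
        nu = np.where(h < 0.5, level, 0.0)
        env = compose_environment(nu, h)
        phi = flat_front_phi(g, 10, 1.0)
        mask = np.zeros(g.shape, bool)
        mask[:, -4:] = True
        traj = run_simulation(
            env,
            ModelParams(dt=0.02),
            g,
            ReservoirSpec(mask, 1.0),
            PhaseState(ScalarField(phi, "phi")),
            [g.insilico_to_hours(units)],
        )
        track = tip_track(traj)
        return track.y_px[0] - track.y_px[-1]

    def test_chemotactic_monotonicity(self):
        # doubling the corridor chemoattractant level must not reduce the
        # time-averaged tip advance
        assert self._corridor_displacement(0.4) >= self._corridor_displacement(0.2)

    def test_immobility_at_low_c0(self):
        from sproutfield.metrics import tip_track
        from sproutfield.scenarios import flat_front_phi

        g = GridSpec(nx=48, ny=48)
        env = compose_environment(np.full(g.shape, 0.05), np.zeros(g.shape))
        phi = flat_front_phi(g, 10, 1.0)
        traj = run_simulation(
            env,
            ModelParams(),  # dt = 1e-3; horizon = 1e5 steps
            g,
            None,
            PhaseState(ScalarField(phi, "phi")),
            [g.insilico_to_hours(100.0)],
        )
        track = tip_track(traj)
        assert abs(track.y_px[-1] - track.y_px[0]) <= 1.0


class TestRunSimulation:
    def _setup(self, grid):
        env = compose_environment(np.zeros(grid.shape), np.zeros(grid.shape))
        phi = np.full(grid.shape, -1.0)
        phi[:, -4:] = 1.0
        return env, PhaseState(ScalarField(phi, "phi"))

    def test_zero_schedule_initial_only(self, grid16):
        env, initial = self._setup(grid16)
        traj = run_simulation(env, ModelParams(), grid16, None, initial, [])
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0].t_h == 0.0
        assert np.array_equal(traj.snapshots[0].phi, initial.phi.values)

    def test_snapshot_times_in_hours(self, grid16):
        env, initial = self._setup(grid16)
        params = ModelParams(dt=1e-2)
        t_h = grid16.insilico_to_hours(1.0)  # 100 steps
        traj = run_simulation(env, params, grid16, None, initial, [t_h])
        assert len(traj.snapshots) == 2
        assert traj.snapshots[1].t_h == pytest.approx(t_h)
        assert traj.snapshots[1].step_index == 100

    def test_reservoir_pinned_in_snapshots(self, grid16):
        env, initial = self._setup(grid16)
        mask = np.zeros(grid16.shape, bool)
        mask[:, -2:] = True
        res = ReservoirSpec(mask, 1.0)
        params = ModelParams(dt=1e-2)
        traj = run_simulation(
            env, params, grid16, res, initial, [grid16.insilico_to_hours(0.5)]
        )
        for s in traj.snapshots:
            assert np.all(s.phi[mask] == 1.0)

    def test_engines_agree_end_to_end(self, grid16):
        env, initial = self._setup(grid16)
        params = ModelParams(dt=1e-2)
        sched = [grid16.insilico_to_hours(0.5)]
        a = run_simulation(env, params, grid16, None, initial, sched, engine="fast")
        b = run_simulation(env, params, grid16, None, initial, sched, engine="numpy")
        assert np.max(np.abs(a.final.phi - b.final.phi)) < 1e-12
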