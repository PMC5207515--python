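"""Spatial operators, time stepping and the simulation driver."""

import numpy as np
import pytest

from gbmsim.fields import StateFields
from gbmsim.fixtures import make_fixture
from gbmsim.grid import Grid
from gbmsim.params import ModelParams
from gbmsim.solver import (ClipTracker, SeedSpec, SimulationConfig,
                           active_transport, initial_state,
                           laplacian_diffusion, simulate, stable_dt, step)


class TestDiffusion:
    def test_constant_field_is_annihilated(self, grid):
        out = laplacian_diffusion(np.full(grid.shape, 0.7), 1e-3, grid)
        assert np.allclose(out, 0.0, atol=1e-18)

    def test_five_point_stencil_on_spike(self, grid):
        G = np.zeros(grid.shape)
        G[20, 20] = 1.0
        delta = 2.5e-4
        out = laplacian_diffusion(G, delta, grid)
        w = delta / grid.h ** 2
        assert out[20, 20] == pytest.approx(-4 * w)
        for i, j in ((19, 20), (21, 20), (20, 19), (20, 21)):
            assert out[i, j] == pytest.approx(w)
        assert np.count_nonzero(out) == 5

    def test_conservation_no_flux(self, grid, rng):
        G = rng.random(grid.shape)
        out = laplacian_diffusion(G, 1e-3, grid)
        assert abs(out.sum()) < 1e-12 * np.abs(G).sum()

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            Grid(nx=10, ny=10, h=0.0)


class TestActiveTransport:
    def test_uniform_B_gives_zero(self, grid, rng):
        G = rng.random(grid.shape)
        out = active_transport(G, np.full(grid.shape, 0.8), 1.4e-3, grid)
        assert np.allclose(out, 0.0, atol=1e-18)

    def test_drift_toward_healthier_tissue(self, grid):
        # on a linear B ramp the glioma blob's center of mass moves up-ramp
        state = make_fixture("linear_B_ramp", grid)
        out = active_transport(state.G, state.B, 1.4e-3, grid)
        x = np.arange(grid.nx)[:, None]
        com_shift = (x * out).sum()   # d/dt of the (unnormalized) first moment
        assert com_shift > 0

    def test_conservation_no_flux(self, grid, rng):
        G = rng.random(grid.shape)
        B = rng.random(grid.shape)
        out = active_transport(G, B, 1.4e-3, grid)
        assert abs(out.sum()) < 1e-12 * np.abs(G).sum()


class TestStableDt:
    def test_reaction_bound_dominates_at_default_motility(self, grid, params):
        state = initial_state(grid, params)
        dt = stable_dt(params, grid, state)
        # diffusion bound h^2/(4 delta) = 750 hr and the advective bound are
        # both far above the reaction-accuracy bound c/(tau+gamma)
        assert dt == pytest.approx(0.5 * 0.25 / (params.tau + params.gamma))

    def test_cap_when_nothing_binds(self, grid):
        p = ModelParams.single_cell(delta=0.0, eta=0.0, tau=0.0, gamma=0.0)
        state = initial_state(grid, p)
        assert stable_dt(p, grid, state, dt_max=6.0) == 6.0

    def test_diffusion_bound_scales_with_h_squared(self, params):
        p = ModelParams.single_cell(tau=0.0, gamma=0.0, eta=0.0)
        g1 = Grid(nx=10, ny=10, h=1.0)
        g2 = Grid(nx=10, ny=10, h=2.0)
        s1, s2 = initial_state(g1, p), initial_state(g2, p)
        assert stable_dt(p, g2, s2, dt_max=1e9) == pytest.approx(
            4 * stable_dt(p, g1, s1, dt_max=1e9))


class TestStep:
    def test_healthy_brain_fixed_point(self, grid, params):
        state = initial_state(grid, params, SeedSpec(shape="none"))
        before = state.copy()
        step(state, params, grid, 0.5)
        # exact up to the exponentially small tanh-switch residual
        assert np.allclose(state.G, before.G, atol=1e-9)
        assert np.allclose(state.B, before.B, atol=1e-9)
        assert np.allclose(state.N, before.N, atol=1e-9)

    def test_mass_conserved_without_mitosis(self, grid, rng):
        # amplitude above the death threshold so necrosis is actually active
        p = ModelParams.single_cell(tau=0.0, sigma=0.0)
        state = initial_state(grid, p, SeedSpec(amplitude=0.25))
        state.G += 0.05 * rng.random(grid.shape)  # roughen the state
        total0 = (state.G + state.B + state.N).sum()
        for _ in range(20):
            step(state, p, grid, 0.25)
            total = (state.G + state.B + state.N).sum()
            assert abs(total - total0) / total0 < 1e-8
            total0 = total

    def test_necrosis_monotone_brain_non_increasing(self, grid, params):
        state = initial_state(grid, params)
        for _ in range(100):
            B_prev, N_prev = state.B.copy(), state.N.copy()
            step(state, params, grid, 0.25)
            assert np.all(state.B <= B_prev + 1e-15)
            assert np.all(state.N >= N_prev - 1e-15)

    def test_dihedral_symmetry_preserved(self, params):
        # a centered radially-symmetric seed on a square grid must stay
        # symmetric under the full 8-fold dihedral group (stencil check)
        g = Grid(nx=41, ny=41)
        state = initial_state(g, params, SeedSpec(center=(20.0, 20.0)))
        for _ in range(200):
            step(state, params, g, 0.25)
        for arr in (state.G, state.B, state.N):
            assert np.abs(arr - arr[::-1, :]).max() < 1e-10
            assert np.abs(arr - arr[:, ::-1]).max() < 1e-10
            assert np.abs(arr - arr.T).max() < 1e-10

    def test_full_solver_matches_ode_oracle_on_flat_state(self):
        # delta = eta = 0 and a spatially uniform state: the PDE solver is
        # an ODE integrator and must track an adaptive reference
        from scipy.integrate import solve_ivp

        from gbmsim.kinetics import reaction_rhs_flat

        p = ModelParams.single_cell(delta=0.0, eta=0.0)
        g = Grid(nx=3, ny=3)
        state = StateFields(G=np.full(g.shape, 0.05), B=np.ones(g.shape),
                            N=np.zeros(g.shape))
        sol = solve_ivp(reaction_rhs_flat, (0.0, 100.0), [0.05, 1.0, 0.0],
                        args=(p,), rtol=1e-10, atol=1e-13, method="LSODA")
        ref = sol.y[:, -1]
        n = int(100.0 / 0.002)
        for _ in range(n):
            step(state, p, g, 0.002)
        got = np.array([state.G[1, 1], state.B[1, 1], state.N[1, 1]])
        assert np.abs(got - ref).max() / np.abs(ref).max() < 1e-4

    def test_clip_tracker_aborts_on_large_loss(self):
        clip = ClipTracker(limit_fraction=1e-6)
        arr = np.array([1.0, -0.1])
        with pytest.raises(FloatingPointError):
            clip.clip(arr, total_mass=1.0, when=0.0, name="G")


class TestSimulate:
    def test_zero_horizon_returns_initial_snapshot_only(self, small_config):
        traj = simulate(small_config.replace(t_max=0.0))
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0].time == 0.0

    def test_snapshot_times_and_series_shape(self, small_config):
        traj = simulate(small_config.replace(t_max=96.0))
        times = traj.series["time_hr"].to_numpy()
        assert np.allclose(times, np.arange(0, 97, 12))
        assert np.all(np.diff(times) > 0)

    def test_deterministic_given_config(self, small_config):
        cfg = small_config.replace(t_max=120.0)
        a = simulate(cfg).series
        b = simulate(cfg).series
        assert a.equals(b)

    def test_untreated_run_develops_layers_in_order(self, small_config):
        # growth milestones appear in radiological order: FLAIR first,
        # then vascular proliferation, then radiological necrosis
        traj = simulate(small_config.replace(t_max=300.0))
        s = traj.series

        def first(col):
            hit = s.index[s[col] > 0]
            return s.loc[hit[0], "time_hr"] if len(hit) else np.inf

        t_f, t_v, t_n = (first(c) for c in
                         ("flair_pct", "vasc_pct", "rad_necrosis_pct"))
        assert t_f <= t_v <= t_n
        assert np.isfinite(t_n)

    def test_no_angiogenesis_means_no_enhancement(self, small_config):
        cfg = small_config.replace(
            params=small_config.params.with_sigma(0.0), t_max=600.0)
        traj = simulate(cfg)
        assert (traj.series["vasc_pct"] == 0).all()

    def test_event_hook_stops_run(self, small_config):
        stopped_at = []

        def hook(state, snap):
            stopped_at.append(snap.time)
            return snap.time >= 48.0

        traj = simulate(small_config, hooks=[hook])
        assert traj.final_state.time == 48.0

    def test_gog_model_end_to_end(self, grid):
        # the two-phenotype comparison baseline: runs, conserves the
        # invariants, and also develops the radiological milestones
        p = ModelParams.gog(delta=2e-4, eta=1.4e-4)
        cfg = SimulationConfig(grid=grid, params=p, t_max=400.0)
        traj = simulate(cfg)
        st = traj.final_state
        st.validate()
        assert (traj.series["flair_pct"].iloc[-1] > 0)
        assert (traj.series["rad_necrosis_pct"].diff().dropna() >= 0).all()
        # only negligible tumor has reached the far corner: the invasive
        # phenotype diffuses there in vanishing amounts, and the
        # proliferative phenotype never moves on its own
        assert st.P[0, 0] < 1e-12 and st.I[0, 0] < 1e-12

    def test_grid_refinement_consistency(self):
        # halving h moves the first enhancement-detection time by < 10%
        def first_vasc(nx, h):
            cfg = SimulationConfig(grid=Grid(nx=nx, ny=nx, h=h), t_max=240.0,
                                   snapshot_interval=4.0)
            s = simulate(cfg).series
            hit = s.index[s["vasc_pct"] > 0]
            return s.loc[hit[0], "time_hr"]

        h = np.sqrt(3.0)
        t_coarse = first_vasc(40, h)
        t_fine = first_vasc(80, h / 2)
        assert abs(t_fine - t_coarse) / t_coarse < 0.10
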