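"""Spatial solver: flux, RHS structure, steppers, conservation, convergence.

The no-decoy reduction is checked against an independent direct
implementation of the three-field system written in this file; it shares no
code with the solver.
"""

import numpy as np
import pytest

from decoychemo import (
    DimensionalParameters,
    build_grid,
    cell_flux,
    initial_state,
    no_decoy_overrides,
    nondimensionalize,
    simulate,
    step_euler,
    step_imex,
)
from decoychemo.spatial import StateFields, rhs


# ---------------------------------------------------------------------------
# independent oracle: the reduced (no-decoy) three-field system, implemented
# directly from its own equations with the same stencils
# ---------------------------------------------------------------------------

def reduced_rhs(n, c, rho_r, p, grid):
    h = grid.h
    inv_h2 = 1.0 / (h * h)

    def grad(f):
        g = np.empty_like(f)
        g[1:-1] = (f[2:] - f[:-2]) / (2 * h)
        g[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * h)
        g[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * h)
        return g

    c_f = c[grid.filter_slice]
    gn, grr = grad(n), grad(rho_r)
    w = p.chi * n * grr
    K = -p.D_n * gn + w
    dn = np.empty_like(n)
    dn[1:-1] = (p.D_n * (n[2:] - 2 * n[1:-1] + n[:-2]) * inv_h2
                - (w[2:] - w[:-2]) / (2 * h))
    dn[0] = -K[0] / p.L
    dn[-1] = K[-1] / p.L
    active = n[1:-1] > 1e-12
    v = np.where(active, K[1:-1] / np.maximum(n[1:-1], 1e-12), 0.0)
    adv = np.zeros_like(rho_r)
    adv[1:-1] = v * grr[1:-1]
    free = 1.0 + (p.beta - 1.0) * rho_r
    drr = -adv + p.k_a1 * c_f * free - (p.k_d1 + p.k_i1) * rho_r
    dc = np.zeros_like(c)
    dc[1:-1] = p.D_c * (c[2:] - 2 * c[1:-1] + c[:-2]) * inv_h2
    dc[0] = 2 * p.D_c * (c[1] - c[0]) * inv_h2
    dc[-1] = 2 * p.D_c * (c[-2] - c[-1]) * inv_h2
    dc[grid.filter_slice] += (p.k_d1 * p.Gamma_r * n * rho_r
                              - p.k_a1 * c_f * n * p.Gamma_r * free)
    return dn, dc, drr


def _random_state(grid, rng, with_decoy=True):
    M, N = grid.n_filter_nodes, grid.n_nodes
    return StateFields(
        t=0.0,
        n=rng.uniform(0.01, 1.0, M),
        c=rng.uniform(0.0, 1.0, N),
        rho_r=rng.uniform(0.0, 5.0, M),
        rho_d=rng.uniform(0.0, 5.0, M) if with_decoy else np.zeros(M),
    )


class TestCellFlux:
    def test_uniform_fields_zero_flux(self, dimless, coarse_grid):
        M = coarse_grid.n_filter_nodes
        K = cell_flux(np.ones(M), np.full(M, 2.0), np.full(M, 3.0),
                      dimless, coarse_grid)
        np.testing.assert_allclose(K, 0.0, atol=1e-12)

    def test_unit_attractant_gradient(self, dimless, coarse_grid):
        M = coarse_grid.n_filter_nodes
        x = np.linspace(0, 1, M)
        K = cell_flux(np.ones(M), x, np.full(M, 0.5), dimless, coarse_grid)
        np.testing.assert_allclose(K, dimless.chi, rtol=1e-10)

    def test_pure_diffusion_of_linear_profile(self, dimless, coarse_grid):
        M = coarse_grid.n_filter_nodes
        x = np.linspace(0, 1, M)
        K = cell_flux(1.0 - x, np.full(M, 0.2), np.full(M, 0.2),
                      dimless, coarse_grid)
        np.testing.assert_allclose(K, dimless.D_n, rtol=1e-10)


class TestRhs:
    def test_zero_state_is_fixed_point(self, dimless, coarse_grid):
        M, N = coarse_grid.n_filter_nodes, coarse_grid.n_nodes
        zero = StateFields(0.0, np.zeros(M), np.zeros(N), np.zeros(M), np.zeros(M))
        for d in rhs(zero, dimless, coarse_grid):
            np.testing.assert_array_equal(d, 0.0)

    def test_reaction_terms_proportional_to_n(self, dimless, coarse_grid):
        state = initial_state(coarse_grid, dimless)
        state.n[:] = 0.0
        dn, dc, drr, drd = rhs(state, dimless, coarse_grid)
        c_f = state.c[coarse_grid.filter_slice]
        # occupancies are driven by binding wherever ligand is present
        np.testing.assert_allclose(drr, dimless.k_a1 * c_f, rtol=1e-12)
        # without cells the ligand evolves by pure diffusion
        pure = rhs(StateFields(0.0, state.n, state.c, 0 * state.rho_r,
                               0 * state.rho_d),
                   dimless.replace(k_a1=0, k_a2=0, k_d1=0, k_d2=0),
                   coarse_grid)[1]
        np.testing.assert_allclose(dc, pure, atol=1e-12)

    def test_no_decoy_reduction_matches_direct_implementation(
            self, dimless, coarse_grid):
        """Zeroing the decoy channel reproduces the reduced system exactly."""
        p = dimless.replace(**no_decoy_overrides())
        rng = np.random.default_rng(7)
        for _ in range(5):
            s = _random_state(coarse_grid, rng, with_decoy=False)
            dn, dc, drr, drd = rhs(s, p, coarse_grid)
            on, oc, orr = reduced_rhs(s.n, s.c, s.rho_r, p, coarse_grid)
            np.testing.assert_allclose(dn, on, atol=1e-12)
            np.testing.assert_allclose(dc, oc, atol=1e-12)
            np.testing.assert_allclose(drr, orr, atol=1e-12)
            np.testing.assert_array_equal(drd, 0.0)

    def test_no_decoy_reduction_over_a_stepped_run(self, params):
        """Node-for-node agreement of the reduced and zero-decoy systems."""
        dimless = nondimensionalize(params).replace(**no_decoy_overrides())
        grid = build_grid(dimless, h=0.05)
        dt = 1e-5
        full = initial_state(grid, dimless)
        n, c, rr = full.n.copy(), full.c.copy(), full.rho_r.copy()
        for k in range(2000):
            new = step_euler(full, dimless, grid, dt)
            on, oc, orr = reduced_rhs(n, c, rr, dimless, grid)
            n, c, rr = n + dt * on, c + dt * oc, rr + dt * orr
            np.clip(n, 0.0, None, out=n)
            np.clip(c, 0.0, None, out=c)
            np.clip(rr, 0.0, None, out=rr)
            full = new
        assert np.max(np.abs(full.n - n)) < 1e-12
        assert np.max(np.abs(full.c - c)) < 1e-12
        assert np.max(np.abs(full.rho_r - rr)) < 1e-12
        assert np.max(np.abs(full.rho_d)) == 0.0

    def test_nan_aborts_with_location(self, dimless, coarse_grid):
        s = initial_state(coarse_grid, dimless)
        s.c[3] = np.nan
        with pytest.raises(FloatingPointError, match="c"):
            rhs(s, dimless, coarse_grid)


class TestInitialState:
    def test_matches_stated_conditions(self, dimless, grid):
        s = initial_state(grid, dimless)
        assert s.n[-1] == 1.0 and np.all(s.n[:-1] == 0.0)
        assert np.trapezoid(s.n, dx=grid.h) == pytest.approx(grid.h / 2)
        assert s.c[0] == 1.0 and s.c[-1] == 0.0
        assert s.c[grid.i0] == 1.0           # ligand reaches the x=0 face
        assert np.all(s.c[grid.i0 + 1:] == 0.0)
        assert np.all(s.rho_r == 0.0) and np.all(s.rho_d == 0.0)


class TestSteppers:
    def test_euler_refuses_unstable_dt(self, dimless, coarse_grid):
        s = initial_state(coarse_grid, dimless)
        bad = 2.0 * dimless.stability_dt(coarse_grid.h)
        with pytest.raises(ValueError, match="stability"):
            step_euler(s, dimless, coarse_grid, bad)
        step_euler(s, dimless, coarse_grid, bad, override_stability=True)

    def test_imex_refuses_oversized_dt(self, dimless, coarse_grid):
        s = initial_state(coarse_grid, dimless)
        with pytest.raises(ValueError, match="dt"):
            step_imex(s, dimless, coarse_grid, 5e-3)

    @pytest.mark.parametrize("stepper", ["euler", "imex"])
    def test_diffusion_only_mass_conserved_one_step(self, dimless, coarse_grid,
                                                    stepper):
        p = dimless.replace(k_a1=0, k_a2=0, k_d1=0, k_d2=0)
        s = initial_state(coarse_grid, p)
        dt = 1e-6 if stepper == "euler" else 1e-4
        step = step_euler if stepper == "euler" else step_imex
        new = step(s, p, coarse_grid, dt)
        m0 = np.trapezoid(s.c, dx=coarse_grid.h)
        m1 = np.trapezoid(new.c, dx=coarse_grid.h)
        assert m1 == pytest.approx(m0, rel=1e-12)

    def test_imex_matches_euler(self, params):
        """Cross-scheme agreement of N_f on a short full-model run."""
        kw = dict(h=0.05, t_max=0.5, snapshot_times=(0.5,))
        eu = simulate(params, stepper="euler", **kw)
        im = simulate(params, stepper="imex", dt=1e-4, **kw)
        assert im.migrated_count() == pytest.approx(eu.migrated_count(),
                                                    rel=5e-3)

    def test_imex_unconditionally_stable_diffusion(self, dimless, coarse_grid):
        p = dimless.replace(k_a1=0, k_a2=0, k_d1=0, k_d2=0)
        s = initial_state(coarse_grid, p)
        for _ in range(50):
            s = step_imex(s, p, coarse_grid, 1e-3)   # far above Euler bound
        assert np.all(np.isfinite(s.c))
        assert np.trapezoid(s.c, dx=coarse_grid.h) == pytest.approx(
            np.trapezoid(initial_state(coarse_grid, p).c, dx=coarse_grid.h),
            rel=1e-10)


class TestConvergence:
    def test_spatial_order_two_on_diffusion(self, dimless):
        """Neumann eigenmode decay is resolved at second order in h."""
        p = dimless.replace(k_a1=0, k_a2=0, k_d1=0, k_d2=0, L_l=2.0, L_u=2.5)
        errors = []
        for h in (0.1, 0.05, 0.025):
            grid = build_grid(p, h=h)
            length = grid.x[-1] - grid.x[0]
            k = np.pi / length
            s = initial_state(grid, p)
            s.c = 1.0 + 0.5 * np.cos(k * (grid.x - grid.x[0]))
            t_end = 2e-4
            dt = 0.2 * p.stability_dt(h)
            steps = int(round(t_end / dt))
            dt = t_end / steps
            for _ in range(steps):
                s = step_euler(s, p, grid, dt)
            exact = 1.0 + 0.5 * np.cos(k * (grid.x - grid.x[0])) * np.exp(
                -p.D_c * k * k * t_end)
            errors.append(np.max(np.abs(s.c - exact)))
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 3.0 < r1 < 5.5 and 3.0 < r2 < 5.5

    def test_temporal_order_one_euler(self, params):
        """Richardson study on the full model: first-order error in dt."""
        dimless = nondimensionalize(params)
        grid = build_grid(dimless, h=0.1)
        # smooth burn-in state so the error is governed by the stepper
        s0 = initial_state(grid, dimless)
        dt_ref = 2.5e-6
        for _ in range(int(round(0.02 / dt_ref))):
            s0 = step_euler(s0, dimless, grid, dt_ref)
        horizon = 0.01

        def advance(state, dt):
            out = state.copy()
            for _ in range(int(round(horizon / dt))):
                out = step_euler(out, dimless, grid, dt)
            return out

        ref = advance(s0, dt_ref)
        errs = [np.max(np.abs(advance(s0, dt).n - ref.n))
                for dt in (4e-5, 2e-5, 1e-5)]
        assert 1.6 < errs[0] / errs[1] < 2.6
        assert 1.6 < errs[1] / errs[2] < 2.9


class TestSimulate:
    def test_deterministic_repetition(self, params, coarse):
        a = simulate(params, t_max=0.2, snapshot_times=(0.2,), **coarse)
        b = simulate(params, t_max=0.2, snapshot_times=(0.2,), **coarse)
        np.testing.assert_array_equal(a.final.n, b.final.n)
        np.testing.assert_array_equal(a.final.c, b.final.c)
        assert a.series.equals(b.series)

    def test_frozen_cells_without_transport(self, params, coarse):
        res = simulate(params, overrides={"chi": 0.0, "mu": 0.0, "D_n": 0.0},
                       t_max=0.2, snapshot_times=(0.2,), **coarse)
        s0 = initial_state(res.grid, res.params_used)
        np.testing.assert_allclose(res.final.n, s0.n, atol=1e-14)

    def test_series_monotone_time_and_metadata(self, params, coarse):
        res = simulate(params, t_max=0.2, snapshot_times=(0.1, 0.2), **coarse)
        assert np.all(np.diff(res.series["t"]) > 0)
        assert res.stepper == "imex" and res.h == pytest.approx(0.05)
        assert [s.t for s in res.snapshots] == [0.1, 0.2]
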