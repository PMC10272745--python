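"""Discretization, integration, conservation and analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import itpk
from itpk import (
    DoseSchedule,
    InfusionEvent,
    SolverError,
    StateVector,
    assemble_rhs,
    build_grid,
    convergence_study,
    simulate,
    total_mass,
)
from itpk.model_core import ConfigurationError, SpinalGeometry

from conftest import single_dose_schedule, stripped_params

EMPTY = DoseSchedule()


class TestGrid:
    def test_reference_spacing(self):
        grid = build_grid(SpinalGeometry(20.0, 0.5, 0.3, 100))
        assert grid.dx == pytest.approx(0.2)
        assert grid.n == 100

    def test_four_cell_centers(self):
        grid = build_grid(SpinalGeometry(20.0, 0.5, 0.3, 4))
        assert grid.x_centers == pytest.approx([2.5, 7.5, 12.5, 17.5])

    def test_cell_volumes_tile_the_channel(self):
        grid = build_grid(SpinalGeometry(20.0, 0.5, 0.3, 37))
        assert 37 * grid.csf_cell_volume == pytest.approx(0.5 * 20.0, rel=1e-12)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            build_grid(SpinalGeometry(20.0, 0.5, 0.3, 1))


class TestRhs:
    def test_zero_state_zero_derivative(self, ref_params):
        y = StateVector.zeros(ref_params.geometry.n_elements_N)
        dy = assemble_rhs(0.0, y, ref_params, EMPTY)
        assert np.all(dy == 0.0)

    def test_discrete_laplacian_of_constant_is_zero(self, ref_params):
        """Uniform C1 with no flow/exchange/clearance must not evolve."""
        p = stripped_params(ref_params, D=0.25)
        y = StateVector.zeros(100)
        y.c1[:] = 3.7
        dy = assemble_rhs(0.0, y, p, EMPTY)
        assert np.max(np.abs(dy)) < 1e-13

    def test_divergence_telescopes_to_boundary_flux(self, ref_params):
        """With a single-cell pulse and pure diffusion the total C1 amount is
        conserved: the discrete divergence sums to the (zero) boundary flux."""
        p = stripped_params(ref_params, D=0.25)
        grid = build_grid(p.geometry)
        y = StateVector.zeros(100)
        y.c1[40] = 5.0
        dy = assemble_rhs(0.0, y, p, EMPTY)
        d_amount = np.sum(dy[:100]) * grid.csf_cell_volume
        assert abs(d_amount) < 1e-12

    def test_nan_state_aborts_with_diagnostic(self, ref_params):
        y = np.full(2 * 100 + 4, np.nan)
        with pytest.raises(SolverError):
            assemble_rhs(0.0, y, ref_params, EMPTY)


class TestSimulate:
    def test_zero_dose_stays_identically_zero(self, ref_params):
        res = simulate(ref_params, EMPTY, 100.0, output_times=[0.0, 50.0, 100.0])
        assert np.all(res.states == 0.0)

    def test_t_end_before_last_event_rejected(self, ref_params):
        with pytest.raises(ConfigurationError):
            simulate(ref_params, single_dose_schedule(), 0.5)

    @pytest.mark.parametrize("flush", [False, True])
    def test_mass_conservation_without_clearance(self, ref_params, flush):
        p = stripped_params(
            ref_params, D=0.1,
            U={(1, 2): 0.2, (1, 5): 0.05, (1, 3): 0.2, (3, 4): 0.1,
               (4, 5): 0.05, (5, 6): 0.5},
            beta={(1, 2): 0.05, (1, 5): 0.02, (3, 4): 0.05, (4, 5): 0.5,
                  (5, 6): 0.2})
        sched = single_dose_schedule(flush=flush)
        res = simulate(p, sched, 2880.0,
                       output_times=[sched.last_event_end, 10.0, 100.0, 2880.0])
        for i, t in enumerate(res.times):
            if t < sched.last_event_end:
                continue
            assert total_mass(res.state_at(i), p) == pytest.approx(
                12000.0, rel=1e-6)

    def test_linearity_in_dose(self, ref_params):
        res1 = simulate(ref_params, single_dose_schedule(dose_ug=6000.0),
                        1440.0, output_times=[1440.0])
        res2 = simulate(ref_params, single_dose_schedule(dose_ug=12000.0),
                        1440.0, output_times=[1440.0])
        assert res2.states[-1] == pytest.approx(2.0 * res1.states[-1],
                                                rel=1e-6, abs=1e-12)

    def test_positivity_of_trajectory(self, ref_params):
        res = simulate(ref_params, single_dose_schedule(volume_ml=4.0),
                       2880.0, output_times=np.linspace(0, 2880, 30))
        assert np.min(res.states) >= 0.0  # clamped only within solver tolerance

    def test_total_mass_hand_value(self, ref_params):
        y = StateVector.zeros(100)
        y.c1[:] = 1.0
        assert total_mass(y, ref_params) == pytest.approx(10.0)  # 1 µg/mL · A·L


class TestAnalyticOracles:
    def test_isolated_compartment_exponential_decay(self, ref_params):
        """A clearance-only compartment decays as C0 e^{-kt}."""
        p = stripped_params(ref_params, k={5: 0.05})
        y0 = StateVector.zeros(100)
        y0.c5 = 8.0
        res = simulate(p, EMPTY, 20.0, output_times=[20.0], initial_state=y0)
        assert res.lumped(5)[0] == pytest.approx(8.0 * np.exp(-0.05 * 20.0),
                                                 rel=1e-6)

    def test_two_box_exchange_matches_brute_force_ode(self, ref_params):
        """One CSF cell exchanging with its tissue cell relaxes to
        C1/C2 = beta, agreeing with a direct 2-ODE integration."""
        beta, U = 0.3, 0.5
        p = stripped_params(ref_params, U={(1, 2): U}, beta={(1, 2): beta},
                            n_elements=2)
        grid = build_grid(p.geometry)
        y0 = StateVector.zeros(2)
        y0.c1[0] = 1.0
        res = simulate(p, EMPTY, 50000.0, output_times=[500.0, 50000.0],
                       initial_state=y0)

        u_cell = U / 2  # per-element exchange coefficient
        vc, vt = grid.csf_cell_volume, grid.tissue_cell_volume

        def rhs(t, y):
            flux = u_cell * (y[0] - beta * y[1])
            return [-flux / vc, flux / vt]

        oracle = solve_ivp(rhs, (0.0, 50000.0), [1.0, 0.0], rtol=1e-10,
                           atol=1e-13, t_eval=[500.0, 50000.0])
        assert res.c1[:, 0] == pytest.approx(oracle.y[0], rel=1e-6)
        assert res.c2[:, 0] == pytest.approx(oracle.y[1], rel=1e-6)
        assert res.c1[-1, 0] / res.c2[-1, 0] == pytest.approx(beta, rel=1e-4)

    def test_pure_diffusion_matches_cosine_series(self, ref_params):
        """Reflecting-boundary diffusion of a smooth bump vs the
        eigenfunction-series solution, L∞ relative error < 1e-3 at N=200."""
        D, L, t_obs, site = 0.1, 20.0, 200.0, 8.0
        p = stripped_params(ref_params, D=D, n_elements=200)
        grid = build_grid(p.geometry)
        bump = InfusionEvent.create(volume_ml=1.0, duration_min=1.0, site_cm=site)
        c0_cells = np.diff(bump.kernel_cdf(grid.x_faces, L)) / grid.dx
        y0 = StateVector.zeros(200)
        y0.c1 = c0_cells
        res = simulate(p, EMPTY, t_obs, output_times=[t_obs], initial_state=y0)

        x = grid.x_centers
        analytic = np.full_like(x, 1.0 / L)
        for n in range(1, 60):
            a_n, _ = quad(lambda xx: bump.kernel(xx, L) * np.cos(n * np.pi * xx / L),
                          site - 2.0, site + 2.0, limit=200)
            a_n *= 2.0 / L
            analytic += (a_n * np.cos(n * np.pi * x / L)
                         * np.exp(-D * (n * np.pi / L) ** 2 * t_obs))
        err = np.max(np.abs(res.c1[0] - analytic)) / np.max(np.abs(analytic))
        assert err < 1e-3


class TestConvergence:
    def test_refinement_strictly_decreases_error(self, ref_params):
        p = stripped_params(ref_params, D=0.1)
        sched = single_dose_schedule(volume_ml=1.0)
        df = convergence_study(p, sched, [25, 50, 100, 200], t_end=60.0)
        assert np.all(np.diff(df.l2_error) < 0.0)

    def test_diffusion_dominated_order_two(self, ref_params):
        p = stripped_params(ref_params, D=0.1)
        sched = single_dose_schedule(volume_ml=0.01, duration_min=1.0, site_cm=8.0)
        df = convergence_study(p, sched, [50, 100, 200], t_end=200.0)
        assert df.observed_order.iloc[-1] == pytest.approx(2.0, abs=0.4)

    def test_advection_dominated_order_one(self, ref_params):
        p = stripped_params(ref_params, D=1e-4)
        sched = single_dose_schedule(volume_ml=2.0, duration_min=10.0, site_cm=5.0)
        df = convergence_study(p, sched, [50, 100, 200], t_end=10.0)
        assert 0.6 <= df.observed_order.iloc[-1] <= 1.5
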