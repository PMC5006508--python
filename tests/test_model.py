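"""Steady-state solver: analytic oracles, conservation laws, Gal3 coupling."""

import numpy as np
import pytest
from scipy.integrate import simpson

from conftest import random_dosage, random_parameters
from galshuttle.model import (
    ConvergenceError,
    DosageConfig,
    Gal3Config,
    ModelParameters,
    SpatialGrid,
    SteadyStateSolution,
    analytic_control_profile,
    hill,
    lacz_readout,
    mass_balance_residuals,
    solve_steady_state,
    solve_with_gal3,
)


class TestHill:
    @pytest.mark.parametrize("n", [1.0, 2.0, 4.7])
    def test_half_max_at_K(self, n):
        assert hill(3.0, K=3.0, n=n) == pytest.approx(0.5)

    def test_zero_at_zero(self):
        assert hill(0.0, K=1.0, n=2.0) == 0.0

    def test_direct_evaluation(self):
        # g = 2K, n = 4: 16/(1+16)
        assert hill(2.0, K=1.0, n=4.0) == pytest.approx(16 / 17, rel=1e-12)

    def test_monotone_and_bounded(self):
        g = np.linspace(0, 50, 500)
        h = hill(g, K=0.7, n=3.0)
        assert np.all(np.diff(h) >= 0)
        assert np.all((h >= 0) & (h <= 1))

    def test_large_argument_saturates(self):
        assert hill(1e300, K=1.0, n=4.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_invalid_g_rejected(self, bad):
        with pytest.raises(ValueError):
            hill(bad, K=1.0, n=2.0)

    def test_invalid_K_n_rejected(self):
        with pytest.raises(ValueError):
            hill(1.0, K=0.0, n=2.0)
        with pytest.raises(ValueError):
            hill(1.0, K=1.0, n=-1.0)


class TestAnalyticControlProfile:
    def test_closed_form_values(self, grid401):
        prof = analytic_control_profile(0.2, 1.0, grid401)
        # cosh(5)/(0.2 sinh 5) = coth(5)/0.2
        assert prof[0] == pytest.approx(1 / (0.2 * np.tanh(5.0)), rel=1e-12)
        assert prof[-1] == pytest.approx(1 / (0.2 * np.sinh(5.0)), rel=1e-12)

    @pytest.mark.parametrize("lam,q", [(0.1, 1.0), (0.2, 0.35), (0.45, 2.0)])
    def test_flux_balance(self, lam, q, grid401):
        prof = analytic_control_profile(lam, q, grid401)
        assert simpson(prof, x=grid401.x) == pytest.approx(q, rel=1e-7)

    def test_invalid_inputs(self, grid401):
        with pytest.raises(ValueError):
            analytic_control_profile(-0.1, 1.0, grid401)
        with pytest.raises(ValueError):
            analytic_control_profile(0.2, 0.0, grid401)


class TestSpatialGrid:
    def test_uniform_construction(self):
        g = SpatialGrid.uniform(101)
        assert g.n_nodes == 101
        assert g.x[0] == 0.0 and g.x[-1] == 1.0
        assert g.h == pytest.approx(0.01)

    def test_rejects_nonuniform(self):
        x = np.linspace(0, 1, 51) ** 1.1
        x /= x[-1]
        with pytest.raises(ValueError):
            SpatialGrid(x)

    def test_rejects_wrong_span(self):
        with pytest.raises(ValueError):
            SpatialGrid(np.linspace(0.1, 1.0, 51))


class TestParameterValidation:
    def test_positive_fields_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(lambda_g=0.0)
        with pytest.raises(ValueError):
            ModelParameters(rho_c=-1.0)

    def test_chi_zero_neutralizes_transport_range(self):
        p = ModelParameters(lambda_g=0.1, chi=0.0, rho_c=3.7)
        # complex decay range equals lambda_g exactly when chi = 0
        assert p.lambda_c / np.sqrt(p.rho_c) == pytest.approx(p.lambda_g)

    def test_q2x_window(self):
        with pytest.raises(ValueError):
            DosageConfig(q_g=1.0, q_r=0.0, q_2x=0.7)

    def test_gal3_domain_ordering(self):
        with pytest.raises(ValueError):
            Gal3Config(domain_start=0.5, domain_end=0.4)


class TestSolverOracle:
    def test_matches_cosh_profile_mu_zero(self, grid401):
        p = ModelParameters(lambda_g=0.2, mu=0.0)
        d = DosageConfig(q_g=1.0, q_r=0.0)
        sol = solve_steady_state(p, d, grid401)
        truth = analytic_control_profile(0.2, 1.0, grid401)
        rel = np.abs(sol.g - truth) / truth
        assert rel.max() < 1e-5
        assert sol.g[0] == pytest.approx(5.00045, abs=5e-5)

    def test_no_repressor_source_gives_control(self, grid401):
        # q_r = 0 with binding enabled: nothing to bind, g is the control
        p = ModelParameters(lambda_g=0.15, mu=50.0, nu=1.0)
        d = DosageConfig(q_g=0.7, q_r=0.0)
        sol = solve_steady_state(p, d, grid401)
        assert np.all(sol.r == 0)
        assert np.all(sol.c == 0)
        truth = analytic_control_profile(0.15, 0.7, grid401)
        assert np.max(np.abs(sol.g - truth) / truth) < 1e-5

    def test_grid_convergence_under_refinement(self):
        # moderately stiff nonlinear solve: halving the spacing must leave
        # the solution essentially unchanged
        p = ModelParameters(lambda_g=0.15, lambda_r=0.1, chi=8.0, mu=50.0,
                            nu=1.0, beta=0.8, rho_c=1.5, K_r=0.05, n_r=2.0)
        d = DosageConfig.two_copy(q_r=2.0)
        g_coarse = solve_steady_state(p, d, SpatialGrid.uniform(201)).g
        sol_fine = solve_steady_state(p, d, SpatialGrid.uniform(401))
        assert np.max(np.abs(sol_fine.g[::2] - g_coarse)) < 1e-4


class TestConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_integral_balances_random_parameters(self, seed, grid401):
        rng = np.random.default_rng(1000 + seed)
        p = random_parameters(rng)
        d = random_dosage(rng)
        sol = solve_steady_state(p, d, grid401)
        res_g, res_r = mass_balance_residuals(sol, p, d)
        assert res_g < 1e-6
        assert res_r < 1e-6

    def test_nonnegative_fields(self, ref_params, grid401):
        for d in (DosageConfig.four_copy(q_r=1.0), DosageConfig.two_copy(q_r=2.0)):
            sol = solve_steady_state(ref_params, d, grid401)
            for field in (sol.g, sol.r, sol.c):
                assert field.min() > -1e-12

    def test_perturbed_solution_violates_balance(self, ref_params, grid401):
        d = DosageConfig.four_copy(q_r=1.0)
        sol = solve_steady_state(ref_params, d, grid401)
        sol.g = sol.g * 1.01  # an unconverged iterate
        res_g, _ = mass_balance_residuals(sol, ref_params, d)
        assert res_g > 1e-6


class TestLaczReadout:
    def test_constant_g_at_K_gives_unity(self, grid201):
        p = ModelParameters(K_z=2.0, n_z=3.0)
        sol = SteadyStateSolution(grid=grid201, g=np.full(201, 2.0),
                                  r=np.zeros(201), c=np.zeros(201),
                                  max_residual=0.0, converged=True)
        assert np.allclose(lacz_readout(sol, p), 1.0)

    def test_monotone_in_g(self, grid201):
        p = ModelParameters(K_z=1.0, n_z=2.0)
        g = np.linspace(3.0, 0.01, 201)
        sol = SteadyStateSolution(grid=grid201, g=g, r=np.zeros(201),
                                  c=np.zeros(201), max_residual=0.0,
                                  converged=True)
        z = lacz_readout(sol, p)
        assert z.max() == pytest.approx(1.0)
        assert np.all(np.diff(z) < 0)

    def test_zero_g_rejected(self, grid201):
        p = ModelParameters()
        sol = SteadyStateSolution(grid=grid201, g=np.zeros(201),
                                  r=np.zeros(201), c=np.zeros(201),
                                  max_residual=0.0, converged=True)
        with pytest.raises(ValueError):
            lacz_readout(sol, p)

    def test_unconverged_solution_rejected(self, grid201):
        p = ModelParameters()
        sol = SteadyStateSolution(grid=grid201, g=np.ones(201),
                                  r=np.zeros(201), c=np.zeros(201),
                                  max_residual=1.0, converged=False)
        with pytest.raises(ValueError):
            lacz_readout(sol, p)

    def test_boundary_from_analytic_control(self, grid401):
        # crossing of the 27%-of-max level located on the analytic profile
        from scipy.optimize import brentq
        from galshuttle.stats import boundary_position

        p = ModelParameters(lambda_g=0.2, K_z=1.0, n_z=2.0, mu=0.0)
        d = DosageConfig(q_g=1.0, q_r=0.0)
        sol = solve_steady_state(p, d, grid401)
        z = lacz_readout(sol, p)
        xl = boundary_position((grid401.x, z), 0.27).x_L

        def z_analytic(x):
            g = np.cosh((1 - x) / 0.2) / (0.2 * np.sinh(1 / 0.2))
            return g**2 / (1 + g**2)

        zmax = max(z_analytic(x) for x in np.linspace(1e-6, 0.2, 50))
        x_true = brentq(lambda x: z_analytic(x) - 0.27 * zmax, 0.05, 0.95)
        assert xl == pytest.approx(x_true, abs=1e-3)


class TestGal3:
    def test_null_perturbation_is_bitwise_identical(self, ref_params, grid201):
        d = DosageConfig.two_copy(q_r=2.0)
        base = solve_steady_state(ref_params, d, grid201)
        gal3 = Gal3Config(q_3=0.0)
        sol = solve_with_gal3(ref_params, d, gal3, grid201)
        assert np.array_equal(sol.g, base.g)
        assert np.array_equal(sol.r, base.r)
        assert np.array_equal(sol.c, base.c)
        assert np.all(sol.s == 0) and np.all(sol.c3 == 0)

    def test_stripe_sequesters_gal80(self, ref_params, grid201):
        d = DosageConfig.two_copy(q_r=2.0)
        base = solve_steady_state(ref_params, d, grid201)
        gal3 = Gal3Config()
        sol = solve_with_gal3(ref_params, d, gal3, grid201)
        x = grid201.x
        dom = (x >= gal3.domain_start) & (x <= gal3.domain_end)
        # Gal80 is depleted and free Gal4 rises inside the stripe
        assert np.all(sol.r[dom] < base.r[dom])
        assert sol.g[dom].max() > base.g[dom].max()
        assert sol.s.max() > 0

    def test_gal3_mass_balance(self, ref_params, grid401):
        d = DosageConfig.two_copy(q_r=2.0)
        gal3 = Gal3Config()
        sol = solve_with_gal3(ref_params, d, gal3, grid401)
        res_g, res_r = mass_balance_residuals(sol, ref_params, d, gal3)
        assert res_g < 1e-6
        # the discontinuous stripe source limits quadrature order for the
        # Gal80 balance
        assert res_r < 1e-5

    def test_shuttling_necessity_contrast(self, ref_params, grid201):
        """A Gal3 stripe boosts the reporter with shuttling but not without."""
        from dataclasses import replace

        d = DosageConfig.two_copy(q_r=2.0)
        gal3 = Gal3Config()
        x = grid201.x
        dom = (x >= gal3.domain_start) & (x <= gal3.domain_end)

        base = solve_steady_state(ref_params, d, grid201)
        z0 = lacz_readout(base, ref_params)
        pert = solve_with_gal3(ref_params, d, gal3, grid201)
        z1 = lacz_readout(pert, ref_params)
        assert (z1 - z0)[dom].max() > 0.05

        p0 = replace(ref_params, chi=0.0)
        base0 = solve_steady_state(p0, d, grid201)
        pert0 = solve_with_gal3(p0, d, gal3, grid201)
        dz = lacz_readout(pert0, p0) - lacz_readout(base0, p0)
        assert np.abs(dz).max() < 0.02


class TestConvergenceFailure:
    def test_error_carries_residual(self, grid201):
        p = ModelParameters(lambda_g=0.1, mu=100.0, nu=0.1, K_r=0.05)
        d = DosageConfig.four_copy(q_r=1.0)
        with pytest.raises(ConvergenceError) as exc_info:
            solve_steady_state(p, d, grid201, max_iter=1)
        assert np.isfinite(exc_info.value.residual)
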