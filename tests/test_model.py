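"""Unit and property tests for the cell-row binding model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ftds.model import (
    AffinityPreset,
    CellRowState,
    ConvergenceError,
    ModelParams,
    Scenario,
    build_fj_profile,
    calibrated_params,
    cell_asymmetry,
    initialize_state,
    integrate_to_steady_state,
    ode_rhs,
    run_scenario,
    summarize_state,
    target_species,
    tissue_gradient,
)


class TestFjProfile:
    def test_linear_profile_anchored_distally(self):
        prof = build_fj_profile(23, 0.03)
        assert prof.n_cells == 23
        assert prof.phi[-1] == 1.0
        np.testing.assert_allclose(np.diff(prof.phi), 0.03)
        assert np.all((prof.phi >= 0) & (prof.phi <= 1))

    def test_zero_slope_is_uniform(self):
        np.testing.assert_array_equal(build_fj_profile(5, 0.0).phi, np.ones(5))

    def test_three_cells_ten_percent(self):
        # hand evaluation of the step rule: 1 - 0.1*(2,1,0)
        np.testing.assert_allclose(build_fj_profile(3, 0.10).phi, [0.8, 0.9, 1.0])

    def test_too_steep_slope_reports_admissible_maximum(self):
        with pytest.raises(ValueError, match="maximum admissible slope"):
            build_fj_profile(23, 0.1)

    @pytest.mark.parametrize("n_cells,slope", [(1, 0.0), (5, -0.1), (5, 1.0)])
    def test_invalid_arguments(self, n_cells, slope):
        with pytest.raises(ValueError):
            build_fj_profile(n_cells, slope)


class TestPresets:
    def test_initial_hierarchy_association_constants(self):
        p = ModelParams(affinity_preset="initial_hierarchy")
        assert [k / koff for k, koff in zip(p.k_on, p.k_off)] == [
            1.0,
            0.25,
            0.25,
            1.0 / 16.0,
        ]

    def test_revised_hierarchy_association_constants(self):
        p = ModelParams(affinity_preset="revised_hierarchy")
        assert [k / koff for k, koff in zip(p.k_on, p.k_off)] == [
            1.0,
            0.5,
            0.25,
            0.25,
        ]

    def test_positive_on_rate_requires_positive_off_rate(self):
        with pytest.raises(ValueError, match="k_off"):
            ModelParams(k_on_A=1.0, k_off_A=0.0)


class TestInitializeState:
    def test_ds_only_split(self):
        params = ModelParams(
            n_cells=2,
            fj_acts_on_ft=False,
            fj_acts_on_ds=True,
            ds_total_per_membrane=100.0,
            ft_total_per_membrane=30.0,
            fj_slope=0.5,
        )
        profile = build_fj_profile(2, 0.5)  # phi = [0.5, 1.0]
        state = initialize_state(params, profile)
        # cell 0 has phi = 0.5: Ds and DsP split evenly, Ft unphosphorylated
        assert state.free[2, 0, 0] == 50.0  # Ds
        assert state.free[3, 0, 0] == 50.0  # DsP
        assert state.free[1, 0, 0] == 0.0  # FtP
        assert state.free[0, 0, 0] == 30.0  # Ft
        assert np.all(state.cplx_p == 0) and np.all(state.cplx_d == 0)

    def test_no_flags_means_no_phosphorylated_species(self):
        params = ModelParams(n_cells=5, fj_acts_on_ft=False, fj_acts_on_ds=False)
        state = initialize_state(params, build_fj_profile(5, 0.03))
        assert np.all(state.free[1] == 0) and np.all(state.free[3] == 0)

    def test_both_flags_give_increasing_phosphorylated_fractions(self):
        params = ModelParams(n_cells=23)
        state = initialize_state(params, build_fj_profile(23, 0.03))
        ftp_frac = state.free[1, :, 0] / (state.free[0, :, 0] + state.free[1, :, 0])
        dsp_frac = state.free[3, :, 0] / (state.free[2, :, 0] + state.free[3, :, 0])
        assert np.all(np.diff(ftp_frac) > 0)
        assert np.all(np.diff(dsp_frac) > 0)

    def test_profile_length_mismatch(self):
        with pytest.raises(ValueError, match="cells"):
            initialize_state(ModelParams(n_cells=5), build_fj_profile(4, 0.0))


class TestOdeRhs:
    def test_single_junction_binding_flux(self):
        # dA_P[1]/dt = k_on_A * FtP[1,P] * Ds[0,D] = 1 * 10 * 8 = 80
        params = ModelParams(
            n_cells=2, k_on_B=0, k_on_C=0, k_on_D=0, diff=0.0
        )
        state = CellRowState.zeros(2)
        state.free[1, 1, 0] = 10.0  # FtP at P membrane of cell 1
        state.free[2, 0, 1] = 8.0  # Ds at D membrane of cell 0
        d = ode_rhs(state, params)
        assert d.cplx_p[0, 1] == pytest.approx(80.0)

    def test_balanced_membranes_have_zero_redistribution_flux(self):
        params = ModelParams(n_cells=3, k_on_A=0, k_on_B=0, k_on_C=0, k_on_D=0,
                             diff=5.0)
        state = CellRowState.zeros(3)
        state.free[:, :, 0] = 7.0
        state.free[:, :, 1] = 7.0
        d = ode_rhs(state, params)
        assert np.all(d.free == 0)

    def test_per_cell_material_derivatives_cancel(self):
        # binding, unbinding and redistribution only move material between
        # pools of the same cell's Ft (or Ds), so the per-cell totals have
        # exactly zero time derivative at any state
        rng = np.random.default_rng(42)
        params = ModelParams(n_cells=3, diff=2.0)
        state = CellRowState.zeros(3)
        state.free[:] = rng.uniform(0, 10, size=state.free.shape)
        state.cplx_p[:, 1:] = rng.uniform(0, 5, size=(4, 2))
        state.cplx_d[:, :-1] = rng.uniform(0, 5, size=(4, 2))
        d = ode_rhs(state, params)
        d_ft = (
            d.free[0].sum(axis=1)
            + d.free[1].sum(axis=1)
            + d.cplx_p.sum(axis=0)
            + d.cplx_d.sum(axis=0)
        )
        np.testing.assert_allclose(d_ft, 0.0, atol=1e-12)
        d_ds = d.free[2].sum(axis=1) + d.free[3].sum(axis=1)
        d_ds[1:] += d.cplx_d[:, :-1].sum(axis=0)
        d_ds[:-1] += d.cplx_p[:, 1:].sum(axis=0)
        np.testing.assert_allclose(d_ds, 0.0, atol=1e-12)

    def test_negative_state_rejected(self):
        params = ModelParams(n_cells=2)
        state = CellRowState.zeros(2)
        state.free[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            ode_rhs(state, params)


class TestSteadyState:
    def test_conservation_through_integration(self):
        params = calibrated_params(n_cells=7)
        state = initialize_state(params, build_fj_profile(7, 0.03))
        ft0 = state.ft_total_per_cell().copy()
        ds0 = state.ds_total_per_cell().copy()
        summary = integrate_to_steady_state(state, params)
        np.testing.assert_allclose(
            summary.state.ft_total_per_cell(), ft0, rtol=1e-6
        )
        np.testing.assert_allclose(
            summary.state.ds_total_per_cell(), ds0, rtol=1e-6
        )

    def test_zero_slope_gives_mirror_symmetric_row(self):
        # without a cue the row has an exact reflection symmetry exchanging
        # proximal and distal; the central cell maps onto itself, so its
        # membranes carry equal bound amounts (terminal cells feed a single
        # junction, so a decaying alternating edge pattern is expected and
        # must itself be mirror symmetric)
        params = calibrated_params(n_cells=7, fj_slope=0.0)
        state = initialize_state(params, build_fj_profile(7, 0.0))
        summary = integrate_to_steady_state(state, params)
        np.testing.assert_allclose(
            summary.bound_ds_P, summary.bound_ds_D[::-1], rtol=1e-6
        )
        np.testing.assert_allclose(
            summary.bound_ft_P, summary.bound_ft_D[::-1], rtol=1e-6
        )
        assert abs(cell_asymmetry(summary, "bound_ds")) < 1e-6
        assert abs(cell_asymmetry(summary, "bound_ft")) < 1e-6

    def test_two_cell_single_complex_matches_algebraic_equilibrium(self):
        # only complex A can form (all Ft phosphorylated, no Ds
        # phosphorylation, other on-rates zero); with diff = 0 each junction
        # orientation is an isolated reversible bimolecular reaction whose
        # equilibrium solves k_on*(F-x)*(D-x) = k_off*x
        ft0, ds0 = 10.0, 8.0
        params = ModelParams(
            n_cells=2,
            k_on_B=0.0, k_on_C=0.0, k_on_D=0.0,
            diff=0.0,
            fj_slope=0.0,
            fj_acts_on_ft=True,
            fj_acts_on_ds=False,
            ft_total_per_membrane=ft0,
            ds_total_per_membrane=ds0,
        )
        state = initialize_state(params, build_fj_profile(2, 0.0))
        summary = integrate_to_steady_state(state, params)
        x_eq = brentq(
            lambda x: (ft0 - x) * (ds0 - x) - x, 0.0, min(ft0, ds0), xtol=1e-14
        )
        assert summary.state.cplx_p[0, 1] == pytest.approx(x_eq, rel=1e-6)
        assert summary.state.cplx_d[0, 0] == pytest.approx(x_eq, rel=1e-6)

    def test_steady_state_independent_of_solver_windowing(self):
        params = calibrated_params(n_cells=5)
        state = initialize_state(params, build_fj_profile(5, 0.03))
        a = integrate_to_steady_state(state, params, rtol=1e-9)
        state2 = initialize_state(params, build_fj_profile(5, 0.03))
        b = integrate_to_steady_state(state2, params, rtol=1e-11)
        np.testing.assert_allclose(a.bound_ds_D, b.bound_ds_D, rtol=1e-6)

    def test_nonconvergence_raises_with_residual(self):
        params = calibrated_params(n_cells=5)
        state = initialize_state(params, build_fj_profile(5, 0.03))
        with pytest.raises(ConvergenceError) as err:
            integrate_to_steady_state(state, params, rtol=1e-12, max_time=1e-3)
        assert err.value.residual > 0


class TestMetrics:
    def test_asymmetry_direct_arithmetic(self):
        state = CellRowState.zeros(3)
        summary = summarize_state(state, ModelParams(n_cells=3))
        summary.bound_ds_D[1] = 11.0
        summary.bound_ds_P[1] = 10.0
        assert cell_asymmetry(summary, "bound_ds", 1) == pytest.approx(10.0)

    def test_asymmetry_zero_when_membranes_equal(self):
        state = CellRowState.zeros(3)
        summary = summarize_state(state, ModelParams(n_cells=3))
        summary.bound_ds_D[1] = summary.bound_ds_P[1] = 4.0
        assert cell_asymmetry(summary, "bound_ds", 1) == 0.0

    def test_terminal_cell_rejected(self):
        state = CellRowState.zeros(3)
        summary = summarize_state(state, ModelParams(n_cells=3))
        with pytest.raises(ValueError, match="terminal"):
            cell_asymmetry(summary, "bound_ds", 0)

    def test_tissue_gradient_geometric_series(self):
        state = CellRowState.zeros(5)
        summary = summarize_state(state, ModelParams(n_cells=5))
        # interior totals [10, 10.3, 10.609] via the Ds-side membranes
        summary.bound_ds_P[1:4] = [10.0, 10.3, 10.609]
        assert tissue_gradient(summary, "per_cell_mean") == pytest.approx(3.0)
        assert tissue_gradient(summary, "end_to_end") == pytest.approx(6.09)

    def test_flat_profile_has_zero_gradient(self):
        # end-to-end vanishes exactly by mirror symmetry; per-cell-mean
        # retains a small positive residue from the symmetric edge
        # oscillation of the finite row (pairs (x-y)/y + (y-x)/x >= 0)
        params = calibrated_params(fj_slope=0.0)
        summary = run_scenario("both_equal", params)
        assert abs(tissue_gradient(summary, "end_to_end")) < 1e-6
        assert abs(tissue_gradient(summary, "per_cell_mean")) < 0.2

    def test_ft_and_ds_sides_count_every_complex_once(self, calibrated_summaries):
        summary = calibrated_summaries["both_equal"]
        assert summary.total_bound("bound_ft").sum() == pytest.approx(
            summary.total_bound("bound_ds").sum(), rel=1e-9
        )


class TestScenarios:
    def test_orientation_ds_distal_ft_proximal(self, calibrated_summaries):
        # with a positive Fj slope the cue polarises every cell the same
        # way -- bound Ds enriched distally, bound Ft proximally -- except
        # within a few cells of the row ends, where the decaying alternating
        # edge pattern locally overrides the ~3% cue
        core = slice(6, -6)
        for summary in calibrated_summaries.values():
            assert np.all(summary.bound_ds_D[core] > summary.bound_ds_P[core])
            assert np.all(summary.bound_ft_P[core] > summary.bound_ft_D[core])

    def test_both_targets_give_strongest_asymmetry(self, calibrated_summaries):
        a_both = cell_asymmetry(calibrated_summaries["both_equal"], "bound_ds")
        a_ds = cell_asymmetry(calibrated_summaries["ds_only"], "bound_ds")
        a_ft = cell_asymmetry(calibrated_summaries["ft_only"], "bound_ft")
        assert a_both > a_ds
        assert a_both > a_ft

    def test_single_target_gradients_have_opposite_signs(self, calibrated_summaries):
        g_ds = tissue_gradient(calibrated_summaries["ds_only"], "end_to_end")
        g_ft = tissue_gradient(calibrated_summaries["ft_only"], "end_to_end")
        assert g_ds < 0 < g_ft

    def test_dual_action_flattens_the_tissue_gradient(self, calibrated_summaries):
        g_both = tissue_gradient(calibrated_summaries["both_equal"], "end_to_end")
        g_ft = tissue_gradient(calibrated_summaries["ft_only"], "end_to_end")
        assert abs(g_both) < abs(g_ft)

    def test_zero_slope_scenario_has_no_asymmetry(self):
        params = calibrated_params(n_cells=7, fj_slope=0.0)
        summary = run_scenario("ds_only", params)
        assert abs(cell_asymmetry(summary, "bound_ds")) < 1e-6

    def test_asymmetry_nondecreasing_in_fj_slope(self):
        # central-cell bound-Ds asymmetry responds monotonically to the cue
        asyms = []
        for slope in (0.0, 0.01, 0.03, 0.05):
            params = calibrated_params(n_cells=9, fj_slope=slope)
            asyms.append(cell_asymmetry(run_scenario("both_equal", params), "bound_ds"))
        assert all(b >= a - 1e-9 for a, b in zip(asyms, asyms[1:]))

    def test_scenario_preset_consistency_enforced(self):
        params = ModelParams(affinity_preset="initial_hierarchy")
        with pytest.raises(ValueError, match="inconsistent"):
            run_scenario("both_ft_biased", params)

    def test_target_species_rule(self):
        assert target_species("ds_only") == "bound_ds"
        assert target_species("ft_only") == "bound_ft"
        assert target_species("both_equal") == "bound_ds"
        assert target_species(Scenario.both_ft_biased) == "bound_ds"
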