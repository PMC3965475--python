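"""Steady-state model, process fluxes, and inverse fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipomet.errors import (
    DegenerateModelError,
    InvalidParameterError,
    UnfittableProfileError,
)
from lipomet.kinetics import (
    FitConfig,
    KineticParameters,
    LipaseShapes,
    ParticleProfile,
    SizeGrid,
    fit_kinetic_parameters,
    process_fluxes,
    smallest_bin_exit_flux,
    steady_state_concentrations,
)

from conftest import random_params

# shapes that make every bin's LPL factor 1 and HL factor ~0, so that
# lambda_i = k_lpl and a_i = k_att exactly (hand-computable cascades)
FLAT_SHAPES = LipaseShapes(lpl_midpoint=-1e3, lpl_scale=1.0,
                           hl_midpoint=-1e3, hl_scale=1.0)


def _uniform_cascade_params(k_lpl=1.0, k_att=1.0):
    return KineticParameters(
        f_prod_total=10.0, prod_mu=60.0, prod_sigma=0.25,
        k_lpl=k_lpl, k_hl=0.0, k_att=k_att, k_upt=max(k_att, 1e-12),
    )


class TestSteadyState:
    def test_three_bin_hand_recursion(self, three_bin_grid):
        """Production 10 into the largest bin, lambda=1 and a=1 everywhere:
        the downward recursion gives concentrations [1.25, 2.5, 5]
        (smallest -> largest)."""
        params = _uniform_cascade_params()
        profile = steady_state_concentrations(
            params, three_bin_grid, FLAT_SHAPES, production=np.array([0.0, 0.0, 10.0])
        )
        np.testing.assert_allclose(profile.bin_concentrations, [1.25, 2.5, 5.0])

    def test_zero_production_gives_zero_concentrations(self, three_bin_grid):
        params = KineticParameters(0.0, 60.0, 0.25, 1.0, 0.0, 1.0, 1.0)
        profile = steady_state_concentrations(params, three_bin_grid, FLAT_SHAPES)
        np.testing.assert_array_equal(profile.bin_concentrations, 0.0)

    def test_global_scale_invariance(self, grid, typical_params):
        base = steady_state_concentrations(typical_params, grid)
        scaled = steady_state_concentrations(typical_params.scaled(3.7), grid)
        np.testing.assert_allclose(
            scaled.bin_concentrations, base.bin_concentrations, rtol=1e-12
        )

    def test_linearity_in_production(self, grid, typical_params):
        from dataclasses import replace

        base = steady_state_concentrations(typical_params, grid)
        doubled = steady_state_concentrations(
            replace(typical_params, f_prod_total=2 * typical_params.f_prod_total), grid
        )
        np.testing.assert_allclose(
            doubled.bin_concentrations, 2 * base.bin_concentrations, rtol=1e-12
        )

    def test_increasing_uptake_decreases_total(self, grid, typical_params):
        from dataclasses import replace

        totals = []
        for k in (0.01, 0.05, 0.25):
            p = replace(typical_params, k_att=k, k_upt=k)
            totals.append(steady_state_concentrations(p, grid).total)
        assert totals[0] > totals[1] > totals[2]

    def test_degenerate_bin_raises(self, three_bin_grid):
        # no lipolysis, no attachment, but production flowing in
        params = KineticParameters(10.0, 60.0, 0.25, 0.0, 0.0, 0.0, 1.0)
        with pytest.raises(DegenerateModelError):
            steady_state_concentrations(params, three_bin_grid, FLAT_SHAPES)

    def test_negative_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParameters(-1.0, 45.0, 0.25, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            KineticParameters(1.0, 45.0, 0.0, 1.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize("n_bins", [10, 37, 100])
    def test_recursion_equals_dense_linear_solve(self, n_bins):
        """The downward recursion solves the same bidiagonal balance system
        a dense linear solver does (oracle equivalence)."""
        rng = np.random.default_rng(n_bins)
        grid = SizeGrid(
            bin_diameters=np.geomspace(19, 80, n_bins),
            subclass_map={"all": (0, n_bins)},
            class_ranges={"VLDL_to_LDL": (0, n_bins), "VLDL_only": (0, n_bins),
                          "IDL_to_LDL": (0, 0)},
        )
        params = random_params(rng)
        shapes = LipaseShapes()
        profile = steady_state_concentrations(params, grid, shapes)
        d = grid.bin_diameters
        lam = params.k_lpl * shapes.f_lpl(d) + params.k_hl * shapes.f_hl(d)
        att = params.k_att * shapes.f_att(d)
        from lipomet.kinetics import production_density

        P = production_density(params, grid)
        A = np.diag(lam + att)
        A[np.arange(n_bins - 1), np.arange(1, n_bins)] = -lam[1:]
        c = np.linalg.solve(A, P)
        np.testing.assert_allclose(profile.bin_concentrations, c, rtol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_mass_conservation(self, grid, seed):
        """Production flux equals uptake flux plus the lipolysis flux
        exiting the smallest bin, to 1e-10 relative."""
        params = random_params(np.random.default_rng(seed))
        profile = steady_state_concentrations(params, grid)
        fx = process_fluxes(params, profile, "VLDL_to_LDL")
        exit_flux = smallest_bin_exit_flux(params, profile)
        assert fx.production == pytest.approx(fx.uptake + exit_flux, rel=1e-10)


class TestProcessFluxes:
    def test_three_bin_whole_grid_fluxes(self, three_bin_grid):
        """Hand computation: total lipolysis 1*5 + 1*2.5 + 1*1.25 = 8.75,
        uptake 8.75, and production 10 = uptake + smallest-bin exit 1.25."""
        params = _uniform_cascade_params()
        production = np.array([0.0, 0.0, 10.0])
        profile = steady_state_concentrations(
            params, three_bin_grid, FLAT_SHAPES, production=production
        )
        fx = process_fluxes(params, profile, "VLDL_to_LDL", FLAT_SHAPES,
                            production=production)
        assert fx.total_lipolysis == pytest.approx(8.75)
        assert fx.uptake == pytest.approx(8.75)
        exit_flux = smallest_bin_exit_flux(params, profile, FLAT_SHAPES)
        assert fx.production == pytest.approx(fx.uptake + exit_flux)
        assert exit_flux == pytest.approx(1.25)

    def test_zero_lpl_zeroes_lpl_flux(self, grid, typical_params):
        from dataclasses import replace

        p = replace(typical_params, k_lpl=0.0)
        profile = steady_state_concentrations(p, grid)
        for range_name in ("VLDL_to_LDL", "VLDL_only", "IDL_to_LDL"):
            assert process_fluxes(p, profile, range_name).lpl_lipolysis == 0.0

    def test_top_range_has_no_boundary_influx(self, grid, typical_params):
        profile = steady_state_concentrations(typical_params, grid)
        for range_name in ("VLDL_to_LDL", "VLDL_only"):
            fx = process_fluxes(typical_params, profile, range_name)
            assert fx.boundary_influx == 0.0
        assert process_fluxes(typical_params, profile, "IDL_to_LDL").boundary_influx > 0

    def test_total_is_lpl_plus_hl(self, grid, typical_params):
        profile = steady_state_concentrations(typical_params, grid)
        for range_name in ("VLDL_to_LDL", "VLDL_only", "IDL_to_LDL"):
            fx = process_fluxes(typical_params, profile, range_name)
            assert fx.total_lipolysis == pytest.approx(
                fx.lpl_lipolysis + fx.hl_lipolysis, rel=1e-12
            )
            assert fx.attachment == fx.uptake

    def test_unknown_range_raises(self, grid, typical_params):
        profile = steady_state_concentrations(typical_params, grid)
        with pytest.raises(KeyError):
            process_fluxes(typical_params, profile, "HDL_only")


class TestFit:
    def test_noise_free_round_trip(self, grid):
        """Fitting a noise-free profile recovers the generating canonical
        parameters to well under 0.1% relative in every component."""
        rng = np.random.default_rng(21)
        for i in range(5):
            truth = random_params(rng)
            profile = steady_state_concentrations(truth, grid)
            fitted, diag = fit_kinetic_parameters(profile, config=FitConfig(seed=i))
            can = truth.canonical()
            for name, value in fitted.as_dict().items():
                assert value == pytest.approx(getattr(can, name), rel=1e-3)
            assert diag.converged

    def test_scale_canonicalization(self, grid, typical_params):
        """A profile generated at f_prod_total = 5x yields canonical
        parameters equal to the generating ones divided by 5x."""
        scaled = typical_params.scaled(5.0)
        profile = steady_state_concentrations(scaled, grid)
        fitted, _ = fit_kinetic_parameters(profile, config=FitConfig(seed=0))
        can = scaled.canonical()  # == typical_params.canonical()
        assert fitted.k_lpl == pytest.approx(can.k_lpl, rel=1e-3)
        assert fitted.f_prod_total == 1.0

    def test_all_zero_profile_unfittable(self, grid):
        obs = {s: 0.0 for s in grid.subclass_names}
        with pytest.raises(UnfittableProfileError):
            fit_kinetic_parameters(obs, grid)

    def test_too_few_nonzero_subclasses_unfittable(self, grid):
        obs = {s: 0.0 for s in grid.subclass_names}
        obs["IDL"] = 100.0
        obs["VLDL_small"] = 50.0
        with pytest.raises(UnfittableProfileError):
            fit_kinetic_parameters(obs, grid)


class TestProfileContainer:
    def test_subclass_sums_match_bins(self, grid, typical_params):
        profile = steady_state_concentrations(typical_params, grid)
        for name, (lo, hi) in grid.subclass_map.items():
            assert profile.subclass_concentrations[name] == pytest.approx(
                profile.bin_concentrations[lo:hi].sum()
            )

    def test_negative_concentration_rejected(self, three_bin_grid):
        with pytest.raises(ValueError):
            ParticleProfile(three_bin_grid, np.array([1.0, -0.5, 2.0]))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SizeGrid(np.array([30.0, 20.0, 40.0]), {"a": (0, 3)},
                     {"VLDL_to_LDL": (0, 3), "VLDL_only": (0, 3), "IDL_to_LDL": (0, 0)})
        with pytest.raises(ValueError):  # gap in the subclass tiling
            SizeGrid(np.array([20.0, 30.0, 40.0]), {"a": (0, 2)},
                     {"VLDL_to_LDL": (0, 3), "VLDL_only": (0, 3), "IDL_to_LDL": (0, 0)})
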