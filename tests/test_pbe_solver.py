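"""Modified PB solver: analytic limits, Gauss-law structure, convergence."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import aptafield as af
from aptafield.layer_model import _E, _EPS0


class TestIonChargeDensity:
    def test_electroneutral_bulk(self, electrolyte):
        assert af.ion_charge_density(0.0, electrolyte) == 0.0

    def test_gouy_chapman_limit(self, point_ion_electrolyte):
        el = point_ion_electrolyte
        rho = af.ion_charge_density(1.0, el)
        assert rho == pytest.approx(-2 * _E * el.n_bulk * np.sinh(1.0), rel=1e-12)

    def test_exclusion_zeroes_density(self, electrolyte):
        assert af.ion_charge_density(3.0, electrolyte, inside_layer=True) == 0.0

    def test_steric_saturation(self, electrolyte):
        # Borukhov form saturates at 2 e n / nu instead of diverging
        nu = electrolyte.steric_nu
        cap = 2 * _E * electrolyte.n_bulk / nu
        for u in (5.0, 50.0, 500.0, 5000.0):
            assert abs(af.ion_charge_density(u, electrolyte)) <= cap
        assert abs(af.ion_charge_density(500.0, electrolyte)) == pytest.approx(
            cap, rel=1e-6
        )

    @given(st.floats(-30, 30))
    @hsettings(max_examples=40, derandomize=True)
    def test_odd_in_potential(self, u):
        el = af.ElectrolyteModel()
        assert af.ion_charge_density(-u, el) == pytest.approx(
            -af.ion_charge_density(u, el), rel=1e-12, abs=1e-18
        )


class TestAnalyticLimits:
    def test_debye_hueckel_small_potential(self, bare_interface,
                                           point_ion_electrolyte, settings):
        el = point_ion_electrolyte
        p = af.solve_pbe(bare_interface, el, 2.0, settings)
        assert p.converged
        dh = 2.0 * np.exp(-p.z_grid / el.debye_length)
        assert np.max(np.abs(p.psi - dh)) / 2.0 < 0.005

    def test_gouy_chapman_nonlinear(self, bare_interface,
                                    point_ion_electrolyte, settings):
        el = point_ion_electrolyte
        p = af.solve_pbe(bare_interface, el, 100.0, settings)
        exact = af.gouy_chapman_potential(p.z_grid, 100.0, el)
        rel = np.max(np.abs(p.psi - exact)) / np.max(np.abs(exact))
        assert rel < 1e-4

    def test_surface_field_debye_hueckel(self, bare_interface,
                                         point_ion_electrolyte, settings):
        el = point_ion_electrolyte
        p = af.solve_pbe(bare_interface, el, 2.0, settings)
        e0 = af.electric_field_at(p, 0.0)
        assert e0 == pytest.approx(2e-3 / el.debye_length, rel=0.01)

    def test_antisymmetry_without_film(self, bare_interface,
                                       point_ion_electrolyte, coarse_settings):
        el = point_ion_electrolyte
        p_pos = af.solve_pbe(bare_interface, el, 150.0, coarse_settings)
        p_neg = af.solve_pbe(bare_interface, el, -150.0, coarse_settings)
        assert np.max(np.abs(p_pos.psi + p_neg.psi)) < 1e-8


class TestBoundaryConditions:
    @pytest.mark.parametrize("psi0", [0.0, 300.0, -300.0])
    def test_electrode_and_far_boundary(self, layer, electrolyte, settings, psi0):
        p = af.solve_pbe(layer, electrolyte, psi0, settings)
        assert p.converged
        kT_e_mV = electrolyte.thermal_voltage * 1e3
        assert abs(p.psi[0] - psi0) <= settings.residual_tol * kT_e_mV
        far_bound = 1e-3 * abs(psi0) if psi0 else 0.01
        assert abs(p.psi[-1]) < far_bound
        assert abs(p.field[-1]) < 1e-6

    def test_overlarge_potential_rejected(self, layer, electrolyte):
        with pytest.raises(af.InvalidParameterError):
            af.solve_pbe(layer, electrolyte, 1500.0)

    def test_field_interpolation_domain(self, layer, electrolyte, coarse_settings):
        p = af.solve_pbe(layer, electrolyte, 100.0, coarse_settings)
        with pytest.raises(af.DomainError):
            af.electric_field_at(p, -0.5)
        with pytest.raises(af.DomainError):
            af.electric_field_at(p, p.z_max + 1.0)

    def test_strict_mode_raises_on_nonconvergence(self, layer, electrolyte):
        starved = af.SolverSettings(grid_spacing=0.01, max_iterations=1,
                                    residual_tol=1e-14)
        with pytest.raises(af.ConvergenceError):
            af.solve_pbe(layer, electrolyte, 300.0, starved, strict=True)
        p = af.solve_pbe(layer, electrolyte, 300.0, starved)
        assert not p.converged


class TestGaussLawStructure:
    """With ions excluded, the in-film field is set by the fixed charge alone."""

    def test_residual_self_consistency(self, layer, electrolyte):
        tight = af.SolverSettings(residual_tol=1e-12)
        p = af.solve_pbe(layer, electrolyte, 300.0, tight)
        # discrete Poisson residual against the total charge density
        h = tight.grid_spacing * 1e-9
        psi_v = p.psi * 1e-3
        lap = (psi_v[2:] - 2 * psi_v[1:-1] + psi_v[:-2]) / h**2
        inside = p.z_grid[1:-1] < layer.total_height
        rho_fix = af.fixed_charge_density(p.z_grid[1:-1], layer, electrolyte)
        rho_ion = np.where(
            inside & layer.exclude_ions, 0.0,
            af.ion_charge_density(p.psi_star[1:-1], electrolyte),
        )
        rhs = -(rho_fix + rho_ion) / (electrolyte.epsilon_r * _EPS0)
        assert np.max(np.abs(lap - rhs)) / np.max(np.abs(rhs)) < 1e-6

    def test_thiol_band_field_constant(self, layer, electrolyte, settings):
        p = af.solve_pbe(layer, electrolyte, 300.0, settings)
        e_low = af.electric_field_at(p, 0.2)
        e_mid = af.electric_field_at(p, 0.5)
        # node at the thiol/linker edge sees half a cell of linker charge
        e_top = af.electric_field_at(p, layer.thiol_height - settings.grid_spacing)
        assert e_mid == pytest.approx(e_low, rel=1e-9)
        assert e_mid == pytest.approx(e_top, rel=1e-9)

    def test_piecewise_linear_with_slope_ratio(self, layer, electrolyte, settings):
        p = af.solve_pbe(layer, electrolyte, 300.0, settings)
        z, e = p.z_grid, p.field

        def band_slope(lo, hi):
            m = (z > lo) & (z < hi)
            coeffs, res = np.polyfit(z[m], e[m], 1, full=True)[:2]
            # linearity: residual tiny relative to the band's field change
            span = abs(coeffs[0]) * (hi - lo)
            assert np.sqrt(res[0] / m.sum()) < 1e-9 + 1e-6 * span
            return coeffs[0]

        s_linker = band_slope(1.05, 14.95)
        s_head = band_slope(15.05, 16.55)
        assert s_head / s_linker == pytest.approx(3.75, rel=1e-3)

    @pytest.mark.parametrize("lo, hi", [(1.0, 15.0), (15.0, 16.59), (1.0, 16.59)])
    def test_band_field_change_equals_enclosed_charge(self, layer, electrolyte,
                                                      settings, lo, hi):
        p = af.solve_pbe(layer, electrolyte, 300.0, settings)
        numeric = af.field_change(p, lo, hi)
        analytic = af.gauss_law_field_change(layer, electrolyte, lo, hi)
        assert numeric == pytest.approx(analytic, rel=1e-3)

    def test_grid_refinement_converged(self, layer, electrolyte):
        d = {}
        for h in (0.01, 0.005):
            p = af.solve_pbe(layer, electrolyte, 300.0,
                             af.SolverSettings(grid_spacing=h))
            d[h] = af.field_change(p, 1.0, 16.6)
        assert abs(d[0.005] - d[0.01]) / d[0.005] < 0.005

    def test_dense_film_field_sign_change(self, layer, electrolyte, settings):
        # +300 mV at sigma = 1e12: positive near the electrode, negative at
        # the film top — the screening signature of the dense layer
        p = af.solve_pbe(layer, electrolyte, 300.0, settings)
        assert af.electric_field_at(p, 1.0) > 0
        assert af.electric_field_at(p, layer.total_height) < 0
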