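"""Film geometry, Manning renormalisation and the piecewise charge density."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import aptafield as af
from aptafield.layer_model import _E


class TestManningFraction:
    @pytest.mark.parametrize(
        "b, lb, expected",
        [
            (0.4, 0.7, 0.57),  # reported value for the TBA backbone
            (0.7, 0.7, 1.0),   # b = l_B: no condensation
            (1.4, 0.7, 1.0),   # capped: cannot exceed full charge
        ],
    )
    def test_values(self, b, lb, expected):
        assert af.manning_fraction(b, lb) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("b, lb", [(0.0, 0.7), (-0.4, 0.7), (0.4, 0.0)])
    def test_nonpositive_inputs_rejected(self, b, lb):
        with pytest.raises(af.InvalidParameterError):
            af.manning_fraction(b, lb)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @hsettings(max_examples=50, derandomize=True)
    def test_monotone_in_spacing_and_capped(self, b1, b2, lb):
        lo, hi = sorted((b1, b2))
        f_lo, f_hi = af.manning_fraction(lo, lb), af.manning_fraction(hi, lb)
        assert 0 < f_lo <= f_hi <= 1.0


class TestBjerrumLength:
    def test_water_at_room_temperature(self):
        assert af.bjerrum_length(78.5, 300.0) == pytest.approx(0.70, abs=0.02)

    def test_inverse_proportionality(self):
        base = af.bjerrum_length(78.5, 300.0)
        assert af.bjerrum_length(157.0, 300.0) == pytest.approx(base / 2, rel=1e-12)
        assert af.bjerrum_length(78.5, 600.0) == pytest.approx(base / 2, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(af.InvalidParameterError):
            af.bjerrum_length(-1.0, 300.0)
        with pytest.raises(af.InvalidParameterError):
            af.bjerrum_length(78.5, 0.0)


class TestDebyeLength:
    def test_physiological_saline_scale(self, electrolyte):
        # 0.1 M 1:1 salt: the textbook ~0.96 nm screening length
        assert af.debye_length(electrolyte) == pytest.approx(0.96, abs=0.02)

    @pytest.mark.parametrize("c, factor", [(0.025, 2.0), (0.4, 0.5)])
    def test_inverse_sqrt_concentration(self, electrolyte, c, factor):
        other = af.ElectrolyteModel(c_bulk=c)
        assert other.debye_length == pytest.approx(
            electrolyte.debye_length * factor, rel=1e-12
        )

    def test_derived_invariants(self, electrolyte):
        assert 0.69 <= electrolyte.bjerrum_length <= 0.72
        assert 0.94 <= electrolyte.debye_length <= 0.98
        assert electrolyte.steric_nu >= 0
        # Borukhov packing fraction: 2 n a^3
        assert electrolyte.steric_nu == pytest.approx(
            2 * electrolyte.n_bulk * (electrolyte.ion_radius * 1e-9) ** 3, rel=1e-12
        )


class TestFixedChargeDensity:
    def test_neutral_thiol_band(self, layer, electrolyte):
        assert af.fixed_charge_density(0.5, layer, electrolyte) == 0.0

    def test_linker_band_magnitude(self, layer, electrolyte):
        # e * f * 35 bases * 1e16 m^-2 / 14 nm with f = 0.57 -> ~ -2.28e6 C/m^3
        rho = af.fixed_charge_density(8.0, layer, electrolyte)
        f = layer.fraction(electrolyte)
        expected = -_E * f * 35 * 1e16 / 14e-9
        assert rho == pytest.approx(expected, rel=1e-12)
        assert rho == pytest.approx(-2.28e6, rel=0.03)

    def test_head_band_denser_by_exact_ratio(self, layer, electrolyte):
        rho_l = af.fixed_charge_density(8.0, layer, electrolyte)
        rho_h = af.fixed_charge_density(16.0, layer, electrolyte)
        assert rho_h == pytest.approx(-8.56e6, rel=0.03)
        assert rho_h / rho_l == pytest.approx((15 / 1.6) / (35 / 14), rel=1e-12)

    def test_outside_and_edges(self, layer, electrolyte):
        # half-open bands: the film top is already outside
        assert af.fixed_charge_density(16.6, layer, electrolyte) == 0.0
        assert af.fixed_charge_density(100.0, layer, electrolyte) == 0.0
        # an interior edge takes the density of the band starting there
        rho_l, rho_h = layer.band_charge_densities(electrolyte)
        assert af.fixed_charge_density(1.0, layer, electrolyte) == rho_l
        assert af.fixed_charge_density(15.0, layer, electrolyte) == rho_h

    def test_negative_z_rejected(self, layer):
        with pytest.raises(af.DomainError):
            af.fixed_charge_density(-0.1, layer)

    def test_everywhere_nonpositive(self, layer, electrolyte):
        z = np.linspace(0, 20, 4001)
        assert np.all(af.fixed_charge_density(z, layer, electrolyte) <= 0)


class TestChargeBookkeeping:
    """Integral of the charge density must equal the renormalised strand charge."""

    @given(
        linker_h=st.floats(0.5, 20.0),
        head_h=st.floats(0.2, 5.0),
        sigma=st.floats(1e10, 1e13),
        linker_bases=st.integers(1, 60),
        head_bases=st.integers(1, 30),
    )
    @hsettings(max_examples=25, derandomize=True, deadline=None)
    def test_band_integral_matches_total(self, linker_h, head_h, sigma,
                                         linker_bases, head_bases):
        lay = af.LayerModel(
            linker_bases=linker_bases, linker_height=linker_h,
            head_bases=head_bases, head_height=head_h, grafting_density=sigma,
        )
        el = af.ElectrolyteModel()
        rho_l, rho_h = lay.band_charge_densities(el)
        integral = rho_l * linker_h * 1e-9 + rho_h * head_h * 1e-9
        assert integral == pytest.approx(lay.total_surface_charge(el), rel=1e-12)

    def test_grid_integration_consistency(self, layer, electrolyte):
        z = np.linspace(0, layer.total_height, 2_000_001)
        rho = af.fixed_charge_density(z, layer, electrolyte)
        integral = np.trapezoid(rho, z * 1e-9)
        assert integral == pytest.approx(
            layer.total_surface_charge(electrolyte), rel=1e-4
        )


class TestCondensedVariant:
    def test_identity(self, layer):
        same = af.condensed_variant(layer, 14.0)
        assert same == layer

    def test_halving_doubles_density_and_conserves_charge(self, layer, electrolyte):
        half = af.condensed_variant(layer, 7.0)
        assert half.total_height == pytest.approx(9.6)
        rho_l0, _ = layer.band_charge_densities(electrolyte)
        rho_l1, _ = half.band_charge_densities(electrolyte)
        assert rho_l1 == pytest.approx(2 * rho_l0, rel=1e-12)
        assert half.total_surface_charge(electrolyte) == pytest.approx(
            layer.total_surface_charge(electrolyte), rel=1e-15
        )

    def test_head_band_shifts_down_unchanged(self, layer, electrolyte):
        half = af.condensed_variant(layer, 7.0)
        assert half.linker_top == pytest.approx(8.0)
        assert half.head_height == layer.head_height
        _, rho_h0 = layer.band_charge_densities(electrolyte)
        _, rho_h1 = half.band_charge_densities(electrolyte)
        assert rho_h1 == rho_h0

    @pytest.mark.parametrize("bad", [0.0, -1.0, 14.5])
    def test_invalid_heights_rejected(self, layer, bad):
        with pytest.raises(af.InvalidParameterError):
            af.condensed_variant(layer, bad)

    def test_aptamer_only_geometry(self, electrolyte):
        short = af.LayerModel.aptamer_only()
        assert short.total_height == pytest.approx(2.6)
        rho_l, rho_h = short.band_charge_densities(electrolyte)
        assert rho_l == 0.0 and rho_h < 0
        # only the 15 head bases contribute
        assert short.total_surface_charge(electrolyte) == pytest.approx(
            -_E * short.fraction(electrolyte) * 15 * short.sigma_m2, rel=1e-12
        )
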