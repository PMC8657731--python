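import dataclasses

import numpy as np
import pytest

from tirekit import materials
from tirekit.dispersion import Cauchy, evaluate_dispersion
from tirekit.optics import (
    Layer,
    NoResonanceError,
    OpticalStack,
    TIRESpectrum,
    default_stack,
    forward_tire,
    reflection_coefficients,
    resonance_wavelength,
)

from oracles import parratt_rp_rs

# frozen after the first validated run (matrix method vs Parratt agreement ~3e-15)
DEFAULT_STACK_RESONANCE_NM = 862.3756821712518


def _random_passive_stack(rng):
    """1-4 layers mixing metals and dielectrics, d in [0, 60] nm, angle 40-75 deg."""
    choices = [
        lambda: materials.gold(),
        lambda: materials.chromium(),
        lambda: Cauchy(a=rng.uniform(1.3, 2.2), b=rng.uniform(0.0, 0.02), k=rng.uniform(0.0, 0.5)),
    ]
    n_layers = rng.integers(1, 5)
    layers = tuple(
        Layer(f"L{i}", rng.uniform(0.0, 60.0), choices[rng.integers(0, 3)]())
        for i in range(n_layers)
    )
    return OpticalStack(
        incidence_medium=materials.bk7(),
        layers=layers,
        exit_medium=materials.water(),
        angle_deg=rng.uniform(40.0, 75.0),
    )


class TestReflectionCoefficients:
    def test_no_interface_reflects_nothing(self):
        water = materials.water()
        st = OpticalStack(water, (), water, angle_deg=68.0)
        rp, rs = reflection_coefficients(st, 700.0)
        assert abs(rp) < 1e-14 and abs(rs) < 1e-14

    def test_lossless_total_internal_reflection_is_unitary(self):
        st = OpticalStack(materials.bk7(), (), materials.water(), angle_deg=68.0)
        for lam in (450.0, 700.0, 1000.0):
            rp, rs = reflection_coefficients(st, lam)
            assert abs(abs(rp) - 1.0) < 1e-10
            assert abs(abs(rs) - 1.0) < 1e-10

    def test_tir_unitarity_survives_lossless_interlayers(self):
        st = OpticalStack(
            materials.bk7(),
            (Layer("film", 30.0, Cauchy(a=1.8)), Layer("film2", 10.0, Cauchy(a=1.45))),
            materials.water(),
            angle_deg=68.0,
        )
        rp, rs = reflection_coefficients(st, 700.0)
        assert abs(abs(rp) - 1.0) < 1e-10
        assert abs(abs(rs) - 1.0) < 1e-10

    def test_matrix_method_matches_parratt_on_random_stacks(self):
        """Oracle equivalence: 100 random passive stacks, agreement < 1e-9."""
        rng = np.random.default_rng(20241)
        for _ in range(100):
            st = _random_passive_stack(rng)
            lam = rng.uniform(450.0, 1000.0)
            rp, rs = reflection_coefficients(st, lam)
            n_media = (
                [evaluate_dispersion(st.incidence_medium, lam)]
                + [evaluate_dispersion(l.dispersion, lam) for l in st.layers]
                + [evaluate_dispersion(st.exit_medium, lam)]
            )
            d = [l.thickness_nm for l in st.layers]
            rp_ref, rs_ref = parratt_rp_rs(n_media, d, st.angle_deg, lam)
            assert abs(rp - rp_ref) < 1e-9
            assert abs(rs - rs_ref) < 1e-9

    def test_passivity_on_random_stacks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            st = _random_passive_stack(rng)
            rp, rs = reflection_coefficients(st, rng.uniform(450.0, 1000.0))
            assert abs(rp) <= 1 + 1e-12
            assert abs(rs) <= 1 + 1e-12

    def test_single_gold_film_against_oracle(self):
        st = OpticalStack(
            materials.bk7(), (Layer("Au", 25.0, materials.gold()),), materials.water(), angle_deg=68.0
        )
        lam = 700.0
        rp, rs = reflection_coefficients(st, lam)
        n_media = [
            evaluate_dispersion(st.incidence_medium, lam),
            evaluate_dispersion(st.layers[0].dispersion, lam),
            evaluate_dispersion(st.exit_medium, lam),
        ]
        rp_ref, rs_ref = parratt_rp_rs(n_media, [25.0], 68.0, lam)
        assert abs(rp - rp_ref) < 1e-10
        assert abs(rs - rs_ref) < 1e-10
        # phase agreement, not only modulus
        assert abs(np.angle(rp) - np.angle(rp_ref)) < 1e-10


class TestForwardModel:
    def test_default_stack_resonance_regression(self, stack):
        spectrum = forward_tire(stack)
        res = resonance_wavelength(spectrum)
        assert res == pytest.approx(DEFAULT_STACK_RESONANCE_NM, abs=1e-6)
        assert 550.0 < res < 900.0

    def test_single_psi_minimum_in_plasmonic_band(self, stack):
        spectrum = forward_tire(stack)
        w, psi = spectrum.wavelengths, spectrum.psi
        band = (w >= 550) & (w <= 900)
        interior = [
            i
            for i in range(1, len(psi) - 1)
            if band[i] and psi[i] < psi[i - 1] and psi[i] < psi[i + 1]
        ]
        assert len(interior) == 1

    def test_delta_swings_down_near_resonance(self, stack):
        spectrum = forward_tire(stack)
        w = spectrum.wavelengths
        delta = np.rad2deg(np.unwrap(np.deg2rad(spectrum.delta)))
        band = (w >= 550) & (w <= 900)
        slopes = np.diff(delta[band]) / np.diff(w[band])
        i = int(np.argmin(slopes))
        descent_at = w[band][i]
        res = resonance_wavelength(spectrum)
        # phase swing sits blue of the (thin-film, broadened) Psi minimum
        assert slopes[i] < -0.3
        assert descent_at < res
        assert res - descent_at < 200.0

    def test_spectral_continuity(self):
        st = dataclasses.replace(
            default_stack(), wavelength_grid=np.arange(450.0, 1000.0 + 1e-9, 1.0)
        )
        spectrum = forward_tire(st)
        assert np.all(np.abs(np.diff(spectrum.psi)) < 0.5)
        delta = np.rad2deg(np.unwrap(np.deg2rad(spectrum.delta)))
        assert np.all(np.abs(np.diff(delta)) < 1.0)

    def test_zero_thickness_layer_is_a_noop(self, stack):
        with_zero = forward_tire(stack.with_thickness("aptamer", 0.0))
        without = forward_tire(stack.without_layer("aptamer"))
        np.testing.assert_allclose(with_zero.psi, without.psi, atol=1e-12)
        np.testing.assert_allclose(with_zero.delta, without.delta, atol=1e-12)

    def test_splitting_a_layer_leaves_the_spectrum_unchanged(self, stack):
        half = Layer("Au_half", 11.5, materials.gold())
        i = stack.layer_index("Au")
        split = dataclasses.replace(
            stack,
            layers=stack.layers[:i] + (half, dataclasses.replace(half, name="Au_half2")) + stack.layers[i + 1 :],
        )
        a, b = forward_tire(stack), forward_tire(split)
        np.testing.assert_allclose(a.psi, b.psi, atol=1e-10)
        np.testing.assert_allclose(a.delta, b.delta, atol=1e-10)


class TestResonanceWavelength:
    def test_symmetric_parabola_returns_the_grid_point(self):
        w = np.arange(600.0, 700.0, 2.0)
        psi = 10.0 + 0.01 * (w - 650.0) ** 2
        spectrum = TIRESpectrum(wavelengths=w, psi=psi, delta=np.full_like(w, 90.0))
        assert resonance_wavelength(spectrum) == pytest.approx(650.0, abs=1e-9)

    def test_red_shift_with_thicker_adlayer(self, stack):
        res_thin = resonance_wavelength(forward_tire(stack.with_thickness("aptamer", 0.0)))
        res_thick = resonance_wavelength(forward_tire(stack.with_thickness("aptamer", 10.0)))
        assert res_thick > res_thin

    def test_strict_monotonicity_over_adlayer_thickness(self, stack):
        res = [
            resonance_wavelength(forward_tire(stack.with_thickness("aptamer", float(d))))
            for d in np.arange(0.0, 20.0 + 1e-9, 1.0)
        ]
        assert np.all(np.diff(res) > 0)

    def test_monotone_spectrum_has_no_resonance(self):
        w = np.arange(600.0, 700.0, 2.0)
        spectrum = TIRESpectrum(
            wavelengths=w, psi=np.linspace(50.0, 20.0, w.size), delta=np.full_like(w, 90.0)
        )
        with pytest.raises(NoResonanceError):
            resonance_wavelength(spectrum)


class TestValidation:
    def test_angle_bounds(self):
        with pytest.raises(ValueError):
            OpticalStack(materials.bk7(), (), materials.water(), angle_deg=95.0)

    def test_wavelength_grid_must_increase(self):
        with pytest.raises(ValueError):
            OpticalStack(
                materials.bk7(), (), materials.water(),
                wavelength_grid=np.array([500.0, 500.0, 600.0]),
            )

    def test_negative_layer_thickness_rejected(self):
        with pytest.raises(ValueError):
            Layer("bad", -1.0, Cauchy(a=1.4))

    def test_grid_outside_material_table_rejected_at_construction(self):
        with pytest.raises(Exception):
            OpticalStack(
                materials.bk7(),
                (Layer("Au", 23.0, materials.gold()),),
                materials.water(),
                wavelength_grid=np.arange(300.0, 500.0, 2.0),
            )

    def test_psi_range_validated(self):
        w = np.arange(500.0, 520.0, 2.0)
        with pytest.raises(ValueError):
            TIRESpectrum(wavelengths=w, psi=np.full_like(w, 95.0), delta=np.zeros_like(w))
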