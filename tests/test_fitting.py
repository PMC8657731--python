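import dataclasses

import numpy as np
import pytest

from tirekit import materials
from tirekit.dispersion import Cauchy
from tirekit.fitting import (
    FitProblem,
    calibrate_metal,
    circular_difference_deg,
    fit_thickness,
    thickness_series,
    _objective,
)
from tirekit.optics import Layer, OpticalStack, default_stack, forward_tire


@pytest.fixture(scope="module")
def fast_stack():
    """Default stack on a 5 nm grid: same physics, quicker optimization tests."""
    return default_stack(wavelength_grid=np.arange(450.0, 1000.0 + 1e-9, 5.0))


def _noisy(spectrum, seed, s_psi=0.1, s_delta=0.5):
    rng = np.random.default_rng(seed)
    return dataclasses.replace(
        spectrum,
        psi=spectrum.psi + rng.normal(0, s_psi, spectrum.psi.shape),
        delta=spectrum.delta + rng.normal(0, s_delta, spectrum.delta.shape),
    )


class TestFitThickness:
    def test_noise_free_round_trip(self, fast_stack):
        measured = forward_tire(fast_stack.with_thickness("aptamer", 7.5))
        result = fit_thickness(
            FitProblem(measured, fast_stack.with_thickness("aptamer", 2.0), {"aptamer": (0.0, 50.0)})
        )
        assert result.thicknesses_nm["aptamer"] == pytest.approx(7.5, abs=1e-3)
        assert result.chi2 < 1e-10
        assert result.converged and not result.non_identifiable

    def test_noisy_thicknesses_keep_their_ordering(self, fast_stack):
        fitted = []
        for i, d_true in enumerate((7.0, 8.0)):
            measured = _noisy(forward_tire(fast_stack.with_thickness("aptamer", d_true)), seed=100 + i)
            result = fit_thickness(FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)}))
            fitted.append(result.thicknesses_nm["aptamer"])
        assert fitted[0] < fitted[1]
        assert 6.5 < fitted[0] < 8.5 and 6.5 < fitted[1] < 8.5

    def test_mean_absolute_error_under_noise(self, fast_stack):
        errors = []
        for seed in range(10):
            measured = _noisy(forward_tire(fast_stack.with_thickness("aptamer", 7.5)), seed)
            result = fit_thickness(FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)}))
            errors.append(abs(result.thicknesses_nm["aptamer"] - 7.5))
        assert np.mean(errors) < 0.5

    def test_objective_minimal_at_truth_for_noise_free_data(self, fast_stack):
        measured = forward_tire(fast_stack.with_thickness("aptamer", 7.5))
        problem = FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)})
        chi2 = _objective(problem, ["aptamer"])
        at_truth = chi2([7.5])
        for d in np.arange(0.0, 50.0 + 1e-9, 0.25):
            assert at_truth <= chi2([d]) + 1e-12

    def test_monotone_signal_mapping(self, fast_stack):
        fitted = []
        for d_true in np.arange(2.0, 15.0 + 1e-9, 1.0):
            measured = forward_tire(fast_stack.with_thickness("aptamer", float(d_true)))
            result = fit_thickness(FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)}))
            fitted.append(result.thicknesses_nm["aptamer"])
        assert np.all(np.diff(fitted) > 0)

    def test_deterministic_results(self, fast_stack):
        measured = _noisy(forward_tire(fast_stack.with_thickness("aptamer", 7.5)), seed=5)
        problem = FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)})
        a, b = fit_thickness(problem), fit_thickness(problem)
        assert a.thicknesses_nm == b.thicknesses_nm
        assert a.chi2 == b.chi2
        np.testing.assert_array_equal(a.residual_psi, b.residual_psi)

    def test_objective_invariant_to_delta_wrap_point(self, fast_stack):
        measured = forward_tire(fast_stack.with_thickness("aptamer", 7.5))
        shifted = dataclasses.replace(measured, delta=(measured.delta + 360.0) % 360.0)
        problem_a = FitProblem(measured, fast_stack, {"aptamer": (0.0, 50.0)})
        problem_b = FitProblem(shifted, fast_stack, {"aptamer": (0.0, 50.0)})
        chi_a = _objective(problem_a, ["aptamer"])([7.5])
        chi_b = _objective(problem_b, ["aptamer"])([7.5])
        assert chi_a == pytest.approx(chi_b, abs=1e-9)

    def test_nonoverlapping_wavelengths_rejected(self, fast_stack):
        measured = forward_tire(fast_stack)
        clipped = dataclasses.replace(
            measured,
            wavelengths=measured.wavelengths + 2000.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            FitProblem(clipped, fast_stack, {"aptamer": (0.0, 50.0)})

    def test_unknown_free_layer_rejected(self, fast_stack):
        measured = forward_tire(fast_stack)
        with pytest.raises(KeyError):
            FitProblem(measured, fast_stack, {"nope": (0.0, 50.0)})

    def test_invalid_bounds_rejected(self, fast_stack):
        measured = forward_tire(fast_stack)
        with pytest.raises(ValueError):
            FitProblem(measured, fast_stack, {"aptamer": (10.0, 5.0)})


class TestCalibrateMetal:
    def test_noise_free_round_trip(self, fast_stack):
        bare = forward_tire(fast_stack.without_layer("aptamer"))
        calibrated = calibrate_metal(bare, fast_stack)
        fitted = {l.name: l.thickness_nm for l in calibrated.layers}
        assert fitted["Cr"] == pytest.approx(4.0, abs=0.01)
        assert fitted["Au"] == pytest.approx(23.0, abs=0.01)
        assert fitted["aptamer"] == 7.5  # untouched

    def test_distinguishes_gold_thicknesses(self, fast_stack):
        fitted_au = []
        for au in (20.0, 25.0):
            bare = forward_tire(fast_stack.without_layer("aptamer").with_thickness("Au", au))
            calibrated = calibrate_metal(bare, fast_stack)
            fitted_au.append({l.name: l.thickness_nm for l in calibrated.layers}["Au"])
        assert fitted_au[1] - fitted_au[0] == pytest.approx(5.0, abs=0.5)

    def test_spectrum_without_plasmon_minimum_warns(self, fast_stack):
        dielectric = OpticalStack(
            materials.bk7(),
            (Layer("film", 10.0, Cauchy(a=1.45)),),
            materials.water(),
            angle_deg=68.0,
            wavelength_grid=fast_stack.wavelength_grid,
        )
        bare = forward_tire(dielectric)
        with pytest.warns(UserWarning, match="non-identifiable"):
            calibrate_metal(bare, fast_stack)


class TestThicknessSeries:
    def test_requires_baseline(self, fast_stack):
        spectrum = forward_tire(fast_stack)
        with pytest.raises(ValueError, match="baseline required"):
            thickness_series([(1e-9, spectrum)], fast_stack)

    def test_baseline_only_series(self, fast_stack):
        spectrum = forward_tire(fast_stack)
        series = thickness_series([(0.0, spectrum)], fast_stack)
        assert len(series.table) == 1
        assert series.table.delta_d_nm.iloc[0] == 0.0

    def test_identical_spectra_give_zero_differences(self, fast_stack):
        spectrum = forward_tire(fast_stack)
        series = thickness_series(
            [(0.0, spectrum), (1e-9, spectrum), (1e-8, spectrum)], fast_stack
        )
        assert np.allclose(series.table.delta_d_nm, 0.0, atol=1e-6)

    def test_compaction_then_pileup_pattern(self, fast_stack, quiet_config):
        from tirekit.synthetic import generate_titration

        cfg = dataclasses.replace(quiet_config, stack=fast_stack)
        series = thickness_series(generate_titration(cfg), fast_stack)
        d = series.table.sort_values("concentration_m").d_nm.to_numpy()
        assert d[1] < d[0] and d[2] < d[1] and d[3] < d[2]  # compaction up to 10 nM
        assert d[4] > d[3]  # pile-up at the top concentration


def test_circular_difference_handles_wrap():
    assert circular_difference_deg(359.0, 1.0) == pytest.approx(-2.0)
    assert circular_difference_deg(1.0, 359.0) == pytest.approx(2.0)
    assert abs(circular_difference_deg(180.0, 0.0)) == pytest.approx(180.0)
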