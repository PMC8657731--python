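"""Inverse problem: layer thicknesses from measured Psi/Delta spectra.

The biolayer thickness d is the quantity of interest; it is recovered by
least-squares matching of the modelled to the measured spectrum,

    chi2(d) = sum_lambda [(Psi_m - Psi_c)/sigma_Psi]^2
            + [circ(Delta_m - Delta_c)/sigma_Delta]^2

where ``circ`` is the minimal circular angular difference, so the 0/360
wrap point of Delta is irrelevant. The biolayer refractive index is held
fixed (Cauchy n = 1.4 + 0.01/lam^2), which resolves the classic
thickness/index trade-off of ellipsometric fitting: only thickness floats.

The optimizer is deterministic by construction: a coarse bounded grid
(0.25 nm) locates the basin, then a derivative-free local search refines
it; ties on the grid break toward the smallest thickness. Metal-film
thicknesses are calibrated once per sample from a bare (no-biolayer)
spectrum and then held fixed for every subsequent biolayer fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from .optics import OpticalStack, TIRESpectrum, _stack_rp_rs, _psi_delta_deg

__all__ = [
    "FitProblem",
    "FitResult",
    "ThicknessSeries",
    "fit_thickness",
    "calibrate_metal",
    "thickness_series",
]

COARSE_STEP_NM = 0.25
DEFAULT_WEIGHTS = (0.1, 0.5)  # (sigma_psi, sigma_delta) in degrees


def circular_difference_deg(a, b):
    """Minimal signed angular difference a - b, in [-180, 180) degrees."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class FitProblem:
    """A measured spectrum, a stack template, and the thicknesses to float."""

    measured: TIRESpectrum
    template: OpticalStack
    free_parameters: dict  # layer name -> (lower_nm, upper_nm)
    weights: tuple[float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("at least one free thickness is required")
        for name, (lo, hi) in self.free_parameters.items():
            self.template.layer_index(name)  # KeyError if absent
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo < hi):
                raise ValueError(f"{name}: bounds must be finite with 0 <= lower < upper")
        if not all(s > 0 for s in self.weights):
            raise ValueError("weights (sigma_psi, sigma_delta) must be positive")
        wm = self.measured.wavelengths
        grid = self.template.wavelength_grid
        if wm[0] > grid[-1] or wm[-1] < grid[0]:
            raise ValueError("measured spectrum and template wavelength ranges do not overlap")


@dataclass(frozen=True)
class FitResult:
    """Fitted thicknesses with approximate (curvature-based) standard errors."""

    thicknesses_nm: dict
    std_errors_nm: dict
    chi2: float
    residual_psi: np.ndarray
    residual_delta: np.ndarray
    converged: bool
    n_evaluations: int
    non_identifiable: bool = False

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


def _model_psi_delta(template: OpticalStack, names, values, wavelengths):
    stack = template
    for name, v in zip(names, values):
        stack = stack.with_thickness(name, float(v))
    rp, rs = _stack_rp_rs(stack, wavelengths)
    return _psi_delta_deg(rp, rs)


def _objective(problem: FitProblem, names):
    wm = problem.measured.wavelengths
    psi_m = problem.measured.psi
    delta_m = problem.measured.delta
    s_psi, s_delta = problem.weights

    def chi2(values):
        psi_c, delta_c = _model_psi_delta(problem.template, names, values, wm)
        r_psi = (psi_m - psi_c) / s_psi
        r_delta = circular_difference_deg(delta_m, delta_c) / s_delta
        return float(np.sum(r_psi**2) + np.sum(r_delta**2))

    return chi2


def fit_thickness(problem: FitProblem) -> FitResult:
    """Recover the free layer thicknesses by weighted least squares.

    Deterministic multi-start: an exhaustive coarse grid (0.25 nm) over the
    bounds, ties broken toward the smallest thickness, followed by bounded
    Powell refinement from the best grid point. Standard errors come from
    the local quadratic approximation of chi2 (finite-difference curvature)
    and are approximate.

    The result is flagged ``non_identifiable`` when the objective is flat
    over the grid or the optimum sits on a bound.
    """
    names = list(problem.free_parameters.keys())
    bounds = [problem.free_parameters[n] for n in names]
    chi2 = _objective(problem, names)
    n_eval = 0

    # coarse grid, ascending per axis so argmin tie-break prefers small thickness
    axes = [
        np.arange(lo, hi + COARSE_STEP_NM / 2, COARSE_STEP_NM).clip(lo, hi)
        for lo, hi in bounds
    ]
    best_val, best_x = np.inf, None
    grid_vals = []
    for point in itertools.product(*axes):
        v = chi2(point)
        n_eval += 1
        grid_vals.append(v)
        if v < best_val:  # strict: first (smallest-thickness) point wins ties
            best_val, best_x = v, np.array(point, dtype=float)
    grid_vals = np.asarray(grid_vals)
    flat = (grid_vals.max() - grid_vals.min()) <= 1e-9 * max(1.0, grid_vals.min())

    res = minimize(
        chi2,
        best_x,
        method="Powell",
        bounds=Bounds([b[0] for b in bounds], [b[1] for b in bounds]),
        options={"xtol": 1e-8, "ftol": 1e-12, "maxiter": 1000},
    )
    n_eval += res.nfev
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    final_chi2 = chi2(x)
    n_eval += 1

    # curvature-based (approximate) standard errors: cov = 2 H^-1
    h = 1e-3
    se = {}
    for i, name in enumerate(names):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        curv = (chi2(xp) - 2.0 * final_chi2 + chi2(xm)) / h**2
        n_eval += 2
        se[name] = float(np.sqrt(2.0 / curv)) if curv > 0 else float("inf")

    at_bound = any(
        x[i] - bounds[i][0] < 1e-9 * (bounds[i][1] - bounds[i][0])
        or bounds[i][1] - x[i] < 1e-9 * (bounds[i][1] - bounds[i][0])
        for i in range(len(names))
    )

    psi_c, delta_c = _model_psi_delta(problem.template, names, x, problem.measured.wavelengths)
    return FitResult(
        thicknesses_nm={n: float(v) for n, v in zip(names, x)},
        std_errors_nm=se,
        chi2=final_chi2,
        residual_psi=problem.measured.psi - psi_c,
        residual_delta=circular_difference_deg(problem.measured.delta, delta_c),
        converged=bool(res.success),
        n_evaluations=n_eval,
        non_identifiable=bool(flat or at_bound),
    )


def calibrate_metal(
    bare_spectrum: TIRESpectrum,
    template: OpticalStack,
    cr_bounds: tuple[float, float] = (1.0, 8.0),
    au_bounds: tuple[float, float] = (15.0, 35.0),
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    biolayer: str = "aptamer",
) -> OpticalStack:
    """Fit Cr and Au thicknesses from a bare (pre-functionalization) spectrum.

    The returned stack is the template with the metal thicknesses replaced
    by their fitted values; these are held fixed for all subsequent
    biolayer fits of the same sample. A bare spectrum with no plasmonic
    minimum leaves the metals unidentifiable; the fit then lands on the
    bounds and the result is flagged through ``fit_thickness``'s
    non-identifiability logic (a UserWarning is raised).
    """
    bare_template = template
    if any(l.name == biolayer for l in template.layers):
        bare_template = template.without_layer(biolayer)
    problem = FitProblem(
        measured=bare_spectrum,
        template=bare_template,
        free_parameters={"Cr": cr_bounds, "Au": au_bounds},
        weights=weights,
    )
    result = fit_thickness(problem)
    if result.non_identifiable:
        import warnings

        warnings.warn(
            "metal calibration is non-identifiable (flat objective or fit at bounds); "
            "check that the bare spectrum shows a plasmon minimum",
            UserWarning,
            stacklevel=2,
        )
    out = template
    for name, value in result.thicknesses_nm.items():
        out = out.with_thickness(name, value)
    return out


@dataclass(frozen=True)
class ThicknessSeries:
    """Per-concentration fitted biolayer thicknesses, referenced to the C=0 baseline."""

    table: pd.DataFrame  # concentration_m, d_nm, d_se_nm, chi2, delta_d_nm
    baseline_d_nm: float


def thickness_series(
    spectra,
    calibrated: OpticalStack,
    biolayer: str = "aptamer",
    bounds: tuple[float, float] = (0.0, 50.0),
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> ThicknessSeries:
    """Fit the biolayer thickness for each spectrum of a titration.

    ``spectra`` is an iterable of (concentration_M, TIRESpectrum); a
    concentration-0 (biolayer-only) baseline must be present. Thickness
    differences are reported relative to that baseline.
    """
    items = sorted(spectra, key=lambda cs: cs[0])
    if not items:
        raise ValueError("no spectra supplied")
    if not any(c == 0 for c, _ in items):
        raise ValueError("thickness_series: baseline required (a concentration-0 spectrum)")
    rows = []
    for c, spectrum in items:
        problem = FitProblem(
            measured=spectrum,
            template=calibrated,
            free_parameters={biolayer: bounds},
            weights=weights,
        )
        result = fit_thickness(problem)
        rows.append(
            {
                "concentration_m": float(c),
                "d_nm": result.thicknesses_nm[biolayer],
                "d_se_nm": result.std_errors_nm[biolayer],
                "chi2": result.chi2,
            }
        )
    table = pd.DataFrame(rows)
    baseline = float(table.loc[table.concentration_m == 0, "d_nm"].iloc[0])
    table["delta_d_nm"] = table["d_nm"] - baseline
    return ThicknessSeries(table=table, baseline_d_nm=baseline)
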