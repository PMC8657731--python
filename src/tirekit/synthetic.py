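"""Instrument emulator: synthetic titration spectra and kinetic sensorgrams.

No raw data accompany the study this pipeline targets, so every input the
analysis consumes is generated here by composing the binding model with the
full optical forward model:

* titration — for each analyte concentration (plus the concentration-0
  baseline) the equilibrium biolayer thickness from the binding isotherm is
  pushed through the multilayer model, giving Psi/Delta spectra whose
  resonance blue-shifts at low concentration (layer compaction) and
  red-shifts at the top concentration (non-specific pile-up);
* sensorgrams — the Langmuir occupancy theta(t) drives the layer thickness
  in time, and Psi at the 700 nm monitoring wavelength is evaluated through
  the full optical model (not a linearized Psi-d shortcut), so downstream
  exponential fits are exercised against the realistic mild nonlinearity of
  the optical response. Above the non-specific onset concentration a slower
  saturating thickness ramp starts once specific binding is 95% complete,
  producing the decay-then-rise biphasic shape.

Noise is independent Gaussian per sample; identical configuration and seed
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import BindingModelParams, equilibrium_thickness
from .kinetics import KineticTrace, langmuir_coverage
from .optics import OpticalStack, TIRESpectrum, _psi_delta_deg, _stack_rp_rs, default_stack

__all__ = [
    "NoiseSpec",
    "GeneratorConfig",
    "generate_titration",
    "generate_trace",
    "generate_bare",
]

# the four titration concentrations of the emulated experiment (M)
DEFAULT_CONCENTRATIONS = (0.09e-9, 0.5e-9, 10e-9, 100e-9)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian instrument noise levels (degrees) and the master seed."""

    sigma_psi: float = 0.1
    sigma_delta: float = 0.5
    sigma_trace: float = 0.02
    sigma_trace_rel: float | None = None  # if set, overrides sigma_trace as a
    # fraction of each trace's noise-free amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_psi, self.sigma_delta, self.sigma_trace) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.sigma_trace_rel is not None and self.sigma_trace_rel < 0:
            raise ValueError("sigma_trace_rel must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to emulate one experiment.

    Defaults reproduce the emulated study's conditions: BK7 / Cr 4 nm /
    Au 23 nm / aptamer 7.5 nm / buffer stack at 68 degrees, analyte
    concentrations 0.09, 0.5, 10 and 100 nM, kinetics monitored at 700 nm
    with ka = 1e6 M^-1 s^-1 and kd = 2.58e-3 s^-1 (K_D = 2.58 nM), traces
    sampled at 1 s for 5 relaxation times (comfortably beyond the 3-tau
    saturation rule).
    """

    stack: OpticalStack = field(default_factory=default_stack)
    binding: BindingModelParams = field(default_factory=BindingModelParams)
    ka: float = 1.0e6       # M^-1 s^-1
    kd: float = 2.58e-3     # s^-1
    concentrations_m: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    trace_wavelength_nm: float = 700.0
    trace_interval_s: float = 1.0
    trace_tau_multiple: float = 5.0
    trace_min_duration_s: float = 120.0
    ns_tau_factor: float = 5.0        # non-specific ramp is this much slower than tau
    ns_onset_completion: float = 0.95  # specific completion fraction triggering the ramp
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_m, dtype=float)
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if not (self.ka > 0 and self.kd > 0):
            raise ValueError("rate constants must be positive")
        if self.trace_tau_multiple < 3.0:
            raise ValueError("trace duration must cover at least 3 relaxation times")
        if self.trace_interval_s <= 0:
            raise ValueError("trace sampling interval must be positive")

    def tau_s(self, concentration_m: float) -> float:
        """Langmuir relaxation time 1/(ka*C + kd) at concentration C."""
        return 1.0 / (self.ka * concentration_m + self.kd)


def _rng_for(config: GeneratorConfig, stream: int, key: int) -> np.random.Generator:
    # deterministic independent stream per generated object
    return np.random.default_rng((int(config.noise.seed) % 2**31, stream, key))


def _psi_for_thickness(config: GeneratorConfig, d_nm: np.ndarray, wavelength_nm: float):
    rp, rs = _stack_rp_rs(
        config.stack, wavelength_nm, aptamer_override=("aptamer", np.asarray(d_nm))
    )
    psi, _ = _psi_delta_deg(rp, rs)
    return psi


def generate_titration(config: GeneratorConfig) -> list[tuple[float, TIRESpectrum]]:
    """Steady-state Psi/Delta spectra at C = 0 (baseline) and each configured C.

    Each spectrum's metadata records the true generating thickness
    (``true_thickness_nm``) and concentration so tests never re-derive
    ground truth from file names.
    """
    concentrations = (0.0,) + tuple(config.concentrations_m)
    out = []
    for i, c in enumerate(concentrations):
        d = equilibrium_thickness(config.binding, c)
        stack = config.stack.with_thickness("aptamer", d)
        rp, rs = _stack_rp_rs(stack, stack.wavelength_grid)
        psi, delta = _psi_delta_deg(rp, rs)
        rng = _rng_for(config, 0, i)
        psi = psi + rng.normal(0.0, config.noise.sigma_psi, psi.shape) if config.noise.sigma_psi else psi
        delta = delta + rng.normal(0.0, config.noise.sigma_delta, delta.shape) if config.noise.sigma_delta else delta
        spectrum = TIRESpectrum(
            wavelengths=stack.wavelength_grid.copy(),
            psi=psi,
            delta=delta,
            metadata={
                "concentration_M": float(c),
                "true_thickness_nm": float(d),
                "angle_deg": float(stack.angle_deg),
                "sample_id": f"synthetic-titration-{i}",
            },
        )
        out.append((float(c), spectrum))
    return out


def generate_bare(config: GeneratorConfig) -> TIRESpectrum:
    """Spectrum of the metal-only stack (before biolayer immobilization).

    This is the input to metal-thickness calibration; true Cr/Au
    thicknesses are recorded in the metadata.
    """
    stack = config.stack.without_layer("aptamer")
    rp, rs = _stack_rp_rs(stack, stack.wavelength_grid)
    psi, delta = _psi_delta_deg(rp, rs)
    rng = _rng_for(config, 2, 0)
    if config.noise.sigma_psi:
        psi = psi + rng.normal(0.0, config.noise.sigma_psi, psi.shape)
    if config.noise.sigma_delta:
        delta = delta + rng.normal(0.0, config.noise.sigma_delta, delta.shape)
    truth = {f"true_{l.name}_nm".lower(): float(l.thickness_nm) for l in stack.layers}
    return TIRESpectrum(
        wavelengths=stack.wavelength_grid.copy(),
        psi=psi,
        delta=delta,
        metadata={"sample_id": "synthetic-bare", "angle_deg": float(stack.angle_deg), **truth},
    )


def generate_trace(config: GeneratorConfig, concentration_m: float) -> KineticTrace:
    """Kinetic sensorgram Psi(t) at the monitoring wavelength for one concentration.

    The specific phase follows the closed-form Langmuir occupancy; above the
    non-specific onset a slower saturating overlayer ramp starts at 95%
    specific completion, producing the biphasic decay-then-rise shape.
    """
    c = float(concentration_m)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    tau = config.tau_s(c)
    duration = max(config.trace_tau_multiple * tau, config.trace_min_duration_s)
    biphasic = c > config.binding.c_on and config.binding.d_ns_max > 0
    t_on = -tau * np.log(1.0 - config.ns_onset_completion)  # ~3 tau at 95%
    tau_ns = config.ns_tau_factor * tau
    if biphasic:
        duration = max(duration, t_on + 6.0 * tau_ns)
    n_samples = int(np.ceil(duration / config.trace_interval_s)) + 1
    times = np.arange(n_samples) * config.trace_interval_s

    theta = langmuir_coverage(c, config.ka, config.kd, times).theta
    d = config.binding.d0 - config.binding.delta_wrap * np.asarray(theta)
    if biphasic:
        excess = max(0.0, c - config.binding.c_on)
        d_ns_eq = config.binding.d_ns_max * excess / (config.binding.k_ns + excess)
        ramp = np.where(
            times > t_on, 1.0 - np.exp(-(np.maximum(times - t_on, 0.0)) / tau_ns), 0.0
        )
        d = d + d_ns_eq * ramp

    psi = _psi_for_thickness(config, d, config.trace_wavelength_nm)
    sigma = config.noise.sigma_trace
    if config.noise.sigma_trace_rel is not None:
        sigma = config.noise.sigma_trace_rel * float(np.ptp(psi))
    if sigma:
        rng = _rng_for(config, 1, int(round(c * 1e15)) % 2**31)
        psi = psi + rng.normal(0.0, sigma, psi.shape)

    return KineticTrace(
        times=times,
        psi=psi,
        concentration_m=c,
        wavelength_nm=config.trace_wavelength_nm,
        metadata={
            "concentration_M": c,
            "wavelength_nm": config.trace_wavelength_nm,
            "true_tau_s": float(tau),
            "true_ka": config.ka,
            "true_kd": config.kd,
            "sigma_trace_deg": float(sigma),
            "sample_id": f"synthetic-trace-{c:.3e}M",
        },
    )
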