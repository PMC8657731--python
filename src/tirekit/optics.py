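"""Forward optical model for prism-coupled (Kretschmann/TIRE) multilayers.

A plane wave travels through a semi-infinite incidence medium (the BK7
prism), crosses a stack of plane-parallel layers (Cr adhesion film, Au
plasmonic film, biomolecular adlayer) and exits into a semi-infinite
aqueous medium. The complex reflection coefficients r_p and r_s are
computed with the characteristic-matrix (Abeles) method, from which the
ellipsometric angles follow:

    tan(Psi) = |r_p| / |r_s|,      Delta = arg(r_p) - arg(r_s)

Beyond the prism/buffer critical angle the Psi spectrum of a thin gold
film shows a surface-plasmon-resonance minimum whose position red-shifts
when the adlayer thickens — the raw observable of the sensing experiment.

Conventions: vacuum wavelengths in nm; complex index n - i*k (k >= 0)
with time dependence exp(-i*omega*t); transverse wavevector branches are
taken with non-negative imaginary part so evanescent and transmitted
fields decay away from the stack. Under this pairing Delta falls sharply
through the plasmon resonance, as ellipsometers in the
total-internal-reflection geometry record. Delta is reported wrapped to
[0, 360) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dispersion import Cauchy, DispersionModel, evaluate_dispersion
from . import materials

__all__ = [
    "Layer",
    "OpticalStack",
    "TIRESpectrum",
    "reflection_coefficients",
    "forward_tire",
    "resonance_wavelength",
    "default_stack",
    "NoResonanceError",
    "NumericDomainError",
]

# layers thinner than this (nm) are dropped before matrix assembly
MIN_THICKNESS_NM = 1e-6


class NoResonanceError(ValueError):
    """Psi spectrum has no interior minimum to locate."""


class NumericDomainError(ArithmeticError):
    """A non-finite intermediate occurred while evaluating the stack."""


@dataclass(frozen=True)
class Layer:
    """A finite-thickness film inside the stack (semi-infinite media are not Layers)."""

    name: str
    thickness_nm: float
    dispersion: DispersionModel

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_nm) or self.thickness_nm < 0:
            raise ValueError(f"layer {self.name!r}: thickness must be finite and >= 0")


@dataclass(frozen=True)
class OpticalStack:
    """Ordered multilayer between two semi-infinite media, light-side first.

    ``angle_deg`` is the planar angle of incidence measured in the
    incidence medium (the 68 degree coupling prism is modelled as a fixed
    planar incidence angle in BK7).
    """

    incidence_medium: DispersionModel
    layers: tuple[Layer, ...]
    exit_medium: DispersionModel
    angle_deg: float = 68.0
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(450.0, 1000.0 + 1e-9, 2.0)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg < 90.0:
            raise ValueError("angle_deg must lie in (0, 90)")
        grid = np.asarray(self.wavelength_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "wavelength_grid", grid)
        # fail fast if any model cannot cover the grid
        for medium, label in self._media_with_labels():
            evaluate_dispersion(medium, grid)

    def _media_with_labels(self):
        yield self.incidence_medium, "incidence_medium"
        for lyr in self.layers:
            yield lyr.dispersion, lyr.name
        yield self.exit_medium, "exit_medium"

    def layer_index(self, name: str) -> int:
        for i, lyr in enumerate(self.layers):
            if lyr.name == name:
                return i
        raise KeyError(f"no layer named {name!r} (have {[l.name for l in self.layers]})")

    def with_thickness(self, name: str, thickness_nm: float) -> "OpticalStack":
        """Return a copy with one layer's thickness replaced."""
        i = self.layer_index(name)
        new_layers = list(self.layers)
        new_layers[i] = replace(new_layers[i], thickness_nm=float(thickness_nm))
        return replace(self, layers=tuple(new_layers))

    def without_layer(self, name: str) -> "OpticalStack":
        i = self.layer_index(name)
        return replace(self, layers=self.layers[:i] + self.layers[i + 1 :])


@dataclass(frozen=True)
class TIRESpectrum:
    """Ellipsometric Psi/Delta spectra on a strictly increasing wavelength grid (degrees)."""

    wavelengths: np.ndarray
    psi: np.ndarray
    delta: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        p = np.asarray(self.psi, dtype=float)
        d = np.asarray(self.delta, dtype=float)
        if not (w.shape == p.shape == d.shape and w.ndim == 1 and w.size >= 1):
            raise ValueError("wavelengths, psi, delta must be equal-length 1-D arrays")
        if w.size > 1 and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.isfinite(p).all() and np.isfinite(d).all()):
            raise ValueError("psi and delta must be finite")
        if np.any(p <= 0) or np.any(p >= 90):
            raise ValueError("psi must lie in (0, 90) degrees")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "psi", p)
        object.__setattr__(self, "delta", np.mod(d, 360.0))


def _alpha(n_complex, sin2_parallel):
    """Normalized transverse wavevector sqrt(n^2 - n0^2 sin^2 theta).

    Evaluated in the conjugate (e^{+iwt}) pairing, where decay away from
    the stack requires Im <= 0; the reflection coefficients are conjugated
    back to the documented n - i*k / e^{-iwt} convention on output.
    """
    a = np.sqrt(np.asarray(n_complex) ** 2 - sin2_parallel + 0j)
    return np.where(a.imag > 0, -a, a)


def _rp_rs_arrays(n_in, angle_deg, layer_n, layer_d_nm, n_exit, wavelength_nm):
    """Broadcastable Abeles characteristic-matrix reflection coefficients.

    ``layer_n`` and ``layer_d_nm`` are parallel sequences (one entry per
    layer) of arrays broadcastable against ``wavelength_nm``; thicknesses
    may themselves carry extra leading axes (used by the thickness-grid
    search in the fitting module).
    """
    theta = np.deg2rad(angle_deg)
    n_in = np.asarray(n_in)
    if np.any(n_in.imag != 0):
        raise NumericDomainError("incidence medium must be transparent (k = 0)")
    sin2 = (n_in.real * np.sin(theta)) ** 2
    k0 = 2.0 * np.pi / np.asarray(wavelength_nm, dtype=float)

    a_in = _alpha(n_in, sin2)
    a_ex = _alpha(n_exit, sin2)
    q_in = {"s": a_in, "p": a_in / n_in**2}
    q_ex = {"s": a_ex, "p": a_ex / np.asarray(n_exit) ** 2}

    out = {}
    for pol in ("s", "p"):
        # characteristic matrix product, light-side first
        m11 = m22 = np.asarray(1.0 + 0j)
        m12 = m21 = np.asarray(0.0 + 0j)
        for n_l, d_nm in zip(layer_n, layer_d_nm):
            n_l = np.asarray(n_l)
            if np.any(n_l == 0):
                raise NumericDomainError("zero refractive index in a layer")
            a_l = _alpha(n_l, sin2)
            q_l = a_l if pol == "s" else a_l / n_l**2
            beta = k0 * np.asarray(d_nm) * a_l
            c, s = np.cos(beta), np.sin(beta)
            l11, l12 = c, 1j * s / q_l
            l21, l22 = 1j * q_l * s, c
            m11, m12, m21, m22 = (
                m11 * l11 + m12 * l21,
                m11 * l12 + m12 * l22,
                m21 * l11 + m22 * l21,
                m21 * l12 + m22 * l22,
            )
        qi, qe = q_in[pol], q_ex[pol]
        num = qi * (m11 + m12 * qe) - (m21 + m22 * qe)
        den = qi * (m11 + m12 * qe) + (m21 + m22 * qe)
        # the matrix product above is assembled in the conjugate (e^{+iwt})
        # pairing where the branch rules are the natural ones; conjugating
        # the result expresses r in the documented n - i*k / e^{-iwt}
        # convention (|r| and Psi unaffected; Delta sign follows the
        # instrument's falling-edge behaviour at resonance)
        out[pol] = np.conj(num / den)
        if not np.isfinite(out[pol]).all():
            raise NumericDomainError(f"non-finite reflection coefficient ({pol}-polarization)")
    return out["p"], out["s"]


def _stack_rp_rs(stack: OpticalStack, wavelength_nm, aptamer_override=None):
    """Evaluate rp, rs for a stack; optionally override one named layer's thickness
    with an array (extra leading axes broadcast against wavelength)."""
    lam = np.asarray(wavelength_nm, dtype=float)
    n_in = evaluate_dispersion(stack.incidence_medium, lam)
    n_ex = evaluate_dispersion(stack.exit_medium, lam)
    layer_n, layer_d = [], []
    for lyr in stack.layers:
        d = lyr.thickness_nm
        if aptamer_override is not None and lyr.name == aptamer_override[0]:
            d = aptamer_override[1]
        if np.ndim(d) == 0 and d < MIN_THICKNESS_NM:
            continue
        try:
            layer_n.append(evaluate_dispersion(lyr.dispersion, lam))
        except Exception as exc:
            raise type(exc)(f"layer {lyr.name!r}: {exc}") from exc
        layer_d.append(d)
    return _rp_rs_arrays(n_in, stack.angle_deg, layer_n, layer_d, n_ex, lam)


def reflection_coefficients(stack: OpticalStack, wavelength_nm):
    """Complex (rp, rs) of the stack at one wavelength (or an array of them).

    Computed by the characteristic-matrix (Abeles) method at the stack's
    incidence angle. For passive stacks (all k >= 0) the moduli never
    exceed 1; with all materials lossless and the angle beyond the
    exit-medium critical angle, |rp| = |rs| = 1 (total internal reflection).
    """
    rp, rs = _stack_rp_rs(stack, wavelength_nm)
    if np.isscalar(wavelength_nm) or np.ndim(wavelength_nm) == 0:
        return complex(np.asarray(rp).item()), complex(np.asarray(rs).item())
    return rp, rs


def _psi_delta_deg(rp, rs):
    psi = np.rad2deg(np.arctan2(np.abs(rp), np.abs(rs)))
    delta = np.rad2deg(np.angle(rp) - np.angle(rs)) % 360.0
    return psi, delta


def forward_tire(stack: OpticalStack, metadata: dict | None = None) -> TIRESpectrum:
    """Model Psi(lambda), Delta(lambda) over the stack's wavelength grid."""
    rp, rs = _stack_rp_rs(stack, stack.wavelength_grid)
    psi, delta = _psi_delta_deg(rp, rs)
    return TIRESpectrum(
        wavelengths=stack.wavelength_grid.copy(),
        psi=psi,
        delta=delta,
        metadata=dict(metadata or {}),
    )


def resonance_wavelength(spectrum: TIRESpectrum) -> float:
    """Wavelength (nm) of the plasmon-resonance minimum of the Psi spectrum.

    Locates the discrete interior minimum and refines it by fitting a
    parabola through the three surrounding points. A minimum sitting on
    the grid edge means no resonance is resolved and raises
    :class:`NoResonanceError`.
    """
    psi = spectrum.psi
    if psi.size < 3:
        raise NoResonanceError("spectrum too short to locate a resonance")
    i = int(np.argmin(psi))
    if i == 0 or i == psi.size - 1:
        raise NoResonanceError("Psi minimum lies on the grid edge; no interior resonance")
    w = spectrum.wavelengths[i - 1 : i + 2]
    y = psi[i - 1 : i + 2]
    a, b, _ = np.polyfit(w - w[1], y, 2)
    if a <= 0:  # flat or degenerate triple: fall back to the grid point
        return float(w[1])
    return float(w[1] - b / (2.0 * a))


def aptamer_cauchy(k: float = 0.0) -> Cauchy:
    """The biolayer dispersion held fixed during fitting: n = 1.4 + 0.01/lam^2 (lam in um)."""
    return Cauchy(a=1.4, b=0.01, c=0.0, k=k)


def default_stack(
    cr_nm: float = 4.0,
    au_nm: float = 23.0,
    aptamer_nm: float = 7.5,
    angle_deg: float = 68.0,
    wavelength_grid: np.ndarray | None = None,
) -> OpticalStack:
    """The default sensor: BK7 prism / Cr / Au / aptamer / buffer at 68 degrees."""
    if wavelength_grid is None:
        wavelength_grid = np.arange(450.0, 1000.0 + 1e-9, 2.0)
    return OpticalStack(
        incidence_medium=materials.bk7(),
        layers=(
            Layer("Cr", cr_nm, materials.chromium()),
            Layer("Au", au_nm, materials.gold()),
            Layer("aptamer", aptamer_nm, aptamer_cauchy()),
        ),
        exit_medium=materials.water(),
        angle_deg=angle_deg,
        wavelength_grid=np.asarray(wavelength_grid, dtype=float),
    )
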