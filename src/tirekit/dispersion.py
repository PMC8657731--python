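"""Wavelength-dependent complex refractive indices for stack materials.

Every material in an optical stack is described by a :class:`DispersionModel`
that maps vacuum wavelength (nm) to a complex refractive index ``n - i*k``.
Three variants cover the materials that occur in a prism-coupled SPR/TIRE
experiment:

* :class:`Cauchy` — transparent dielectrics and biomolecular layers,
  ``n(lambda) = A + B/lambda^2 + C/lambda^4`` with *lambda in micrometres*
  (the convention under which A=1.4, B=0.01 gives n≈1.42 near 700 nm).
* :class:`Sellmeier` — three-term glass dispersion (BK7 prism).
* :class:`Tabulated` — measured (wavelength, n, k) tables for metals,
  linearly interpolated and strictly range-checked.

The sign convention is ``n - i*k`` with k >= 0 for absorbing media; the
optics code is written so that passivity (|r| <= 1) holds for any stack
built from these models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "Cauchy",
    "Sellmeier",
    "Tabulated",
    "DispersionModel",
    "evaluate_dispersion",
]

NM_PER_UM = 1000.0


class DispersionRangeError(ValueError):
    """Wavelength query outside the supported range of a dispersion model."""


@dataclass(frozen=True)
class Cauchy:
    """Cauchy dispersion n = A + B/lam^2 + C/lam^4 (lam in um), constant extinction k."""

    a: float
    b: float = 0.0  # um^2
    c: float = 0.0  # um^4
    k: float = 0.0  # extinction, wavelength-independent

    def __post_init__(self) -> None:
        if not np.isfinite([self.a, self.b, self.c, self.k]).all():
            raise ValueError("Cauchy coefficients must be finite")
        if self.k < 0:
            raise ValueError("extinction coefficient k must be >= 0")

    def __call__(self, wavelength_nm):
        lam_um = np.asarray(wavelength_nm, dtype=float) / NM_PER_UM
        if np.any(lam_um <= 0):
            raise DispersionRangeError("wavelength must be positive")
        n = self.a + self.b / lam_um**2 + self.c / lam_um**4
        return n - 1j * self.k * np.ones_like(n)


@dataclass(frozen=True)
class Sellmeier:
    """Three-term Sellmeier: n^2 = 1 + sum_i B_i lam^2 / (lam^2 - C_i), lam in um, C_i in um^2."""

    b: tuple[float, float, float]
    c: tuple[float, float, float]

    def __call__(self, wavelength_nm):
        lam2 = (np.asarray(wavelength_nm, dtype=float) / NM_PER_UM) ** 2
        if np.any(lam2 <= 0):
            raise DispersionRangeError("wavelength must be positive")
        n2 = 1.0 + sum(bi * lam2 / (lam2 - ci) for bi, ci in zip(self.b, self.c))
        if np.any(n2 <= 0):
            raise DispersionRangeError("Sellmeier model evaluated outside its physical range")
        return np.sqrt(n2) - 0j


@dataclass(frozen=True)
class Tabulated:
    """Measured optical constants on a sorted wavelength grid, linearly interpolated.

    Queries outside ``[wavelengths[0], wavelengths[-1]]`` raise
    :class:`DispersionRangeError` — metals' optical constants cannot be
    safely extrapolated.
    """

    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray
    name: str = "tabulated"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if not (w.ndim == 1 and w.size >= 2 and w.size == n.size == k.size):
            raise ValueError("tabulated model needs >= 2 rows of equal-length columns")
        if np.any(np.diff(w) <= 0):
            raise ValueError("tabulated wavelengths must be strictly increasing")
        if np.any(n <= 0) or np.any(k < 0):
            raise ValueError("tabulated model requires n > 0 and k >= 0")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    def __call__(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise DispersionRangeError(
                f"wavelength outside tabulated range [{lo:g}, {hi:g}] nm for {self.name!r}"
            )
        n = np.interp(lam, self.wavelengths_nm, self.n)
        k = np.interp(lam, self.wavelengths_nm, self.k)
        return n - 1j * k


DispersionModel = Union[Cauchy, Sellmeier, Tabulated]


def evaluate_dispersion(model: DispersionModel, wavelength_nm) -> complex | np.ndarray:
    """Evaluate a dispersion model at one or more wavelengths (nm).

    Returns the complex index ``n - i*k``. Scalar in, scalar out.

    >>> round(evaluate_dispersion(Cauchy(a=1.4, b=0.01), 700.0).real, 2)
    1.42
    """
    out = model(wavelength_nm)
    if np.isscalar(wavelength_nm) or np.ndim(wavelength_nm) == 0:
        return complex(np.asarray(out).item())
    return np.asarray(out)
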