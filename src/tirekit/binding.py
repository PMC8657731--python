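"""Concentration -> equilibrium biolayer thickness model.

Receptor aptamers stand on the gold surface as a brush of thickness ``d0``
(7-8 nm for freshly immobilized, stretched molecules). Specific capture of
the RNA target makes the aptamers wrap around it, compacting the layer: the
thickness loss follows the Langmuir occupancy C/(C + K_D), saturating at
``delta_wrap``. Once the specific sites approach saturation, further analyte
accumulates non-specifically on top of the completed layer; this pile-up is
modelled as a second saturating overlayer that switches on at ``c_on`` and
grows toward ``d_ns_max`` with half-saturation ``k_ns``. The net curve
reproduces the experimental signature: thickness (and hence the resonance
wavelength) first decreases with concentration, then increases at high
concentration.

A linear, unbounded non-specific term was rejected: physically the
overlayer cannot grow without limit, and an unbounded term would make the
model thickness diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BindingModelParams", "equilibrium_thickness", "saturation_concentration"]


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the specific-wrap + non-specific-overlayer thickness model.

    All concentrations in molar (M), thicknesses in nm.
    """

    d0: float = 7.5           # bare aptamer-layer thickness
    delta_wrap: float = 2.0   # maximal specific thickness decrease
    kd_affinity: float = 2.58e-9   # equilibrium dissociation constant K_D
    d_ns_max: float = 3.5     # ceiling of the non-specific overlayer
    c_on: float = 10e-9       # onset concentration of non-specific pile-up
    k_ns: float = 50e-9       # half-saturation of the overlayer (above onset)

    def __post_init__(self) -> None:
        if not (self.d0 > self.delta_wrap >= 0):
            raise ValueError("require d0 > delta_wrap >= 0")
        if self.kd_affinity <= 0 or self.c_on <= 0 or self.k_ns <= 0:
            raise ValueError("K_D, c_on and k_ns must be positive concentrations")
        if self.d_ns_max < 0:
            raise ValueError("d_ns_max must be >= 0")


def equilibrium_thickness(params: BindingModelParams, concentration_m) -> float | np.ndarray:
    """Equilibrium layer thickness d(C) in nm at analyte concentration C (M).

    d(C) = d0 - delta_wrap * C/(C + K_D)
              + d_ns_max * max(0, C - c_on) / (k_ns + max(0, C - c_on))

    Continuous in C, bounded below by d0 - delta_wrap and above by
    d0 - delta_wrap + d_ns_max.
    """
    c = np.asarray(concentration_m, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    specific = params.delta_wrap * c / (c + params.kd_affinity)
    excess = np.maximum(0.0, c - params.c_on)
    nonspecific = params.d_ns_max * excess / (params.k_ns + excess)
    d = params.d0 - specific + nonspecific
    return float(d) if np.ndim(concentration_m) == 0 else d


def saturation_concentration(params: BindingModelParams, fraction: float) -> float:
    """Concentration at which specific occupancy reaches ``fraction``.

    Inverts C/(C + K_D) = fraction, giving C = K_D * fraction / (1 - fraction);
    fraction = 0.5 returns K_D by definition of half-saturation.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    return params.kd_affinity * fraction / (1.0 - fraction)
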