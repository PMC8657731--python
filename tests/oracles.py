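"""Independent reference implementations used only to cross-check tirekit.

The Parratt-style recursive reflectivity below is coded directly from the
interface Fresnel coefficients and the bottom-up recursion — deliberately a
different algorithm from the characteristic-matrix product in
``tirekit.optics`` — under the same conventions (complex index n - i*k;
the recursion runs in the conjugate e^{+iwt} pairing with transverse
wavevector branch Im <= 0 and the result is conjugated back, mirroring the
documented output convention).
"""

from __future__ import annotations

import numpy as np


def _kz(n_complex: complex, n0_sin_theta: float, k0: float) -> complex:
    a = np.sqrt(complex(n_complex) ** 2 - n0_sin_theta**2)
    if a.imag > 0:
        a = -a
    return k0 * a


def parratt_rp_rs(
    n_media: list[complex],
    d_nm: list[float],
    angle_deg: float,
    wavelength_nm: float,
) -> tuple[complex, complex]:
    """Reflection coefficients of a stratified medium by Parratt recursion.

    ``n_media`` lists the complex indices from the incidence medium to the
    exit medium inclusive; ``d_nm`` the thicknesses of the interior layers
    (len(n_media) - 2 entries).
    """
    assert len(n_media) == len(d_nm) + 2
    k0 = 2.0 * np.pi / wavelength_nm
    n0_sin = n_media[0].real * np.sin(np.deg2rad(angle_deg))
    kz = [_kz(n, n0_sin, k0) for n in n_media]

    def fresnel(i: int, pol: str) -> complex:
        ni, nj = n_media[i], n_media[i + 1]
        if pol == "s":
            return (kz[i] - kz[i + 1]) / (kz[i] + kz[i + 1])
        return (nj**2 * kz[i] - ni**2 * kz[i + 1]) / (nj**2 * kz[i] + ni**2 * kz[i + 1])

    out = {}
    for pol in ("p", "s"):
        r = fresnel(len(n_media) - 2, pol)  # deepest interface
        for i in range(len(n_media) - 3, -1, -1):
            phase = np.exp(-2j * kz[i + 1] * d_nm[i])
            rf = fresnel(i, pol)
            r = (rf + r * phase) / (1.0 + rf * r * phase)
        out[pol] = np.conj(r)
    return out["p"], out["s"]
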