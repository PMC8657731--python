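"""Regenerate the packaged Au and Cr optical-constant tables.

The tables (src/tirekit/data/{au,cr}_nk.csv, 400-1000 nm, 5 nm step) are
computed from standard analytic fits to literature optical constants:

* Au — the Drude + two-critical-point model of Etchegoin, Le Ru & Meyer,
  J. Chem. Phys. 125, 164705 (2006) (erratum 127, 189901 (2007)), which
  closely tracks the Johnson & Christy (1972) data across 450-1000 nm;
* Cr — the Lorentz-Drude parameterization of Rakic, Djurisic, Elazar &
  Majewski, Appl. Opt. 37, 5271 (1998).

Run from the repository root:

    python scripts/build_material_tables.py
"""

from pathlib import Path

import numpy as np

HC_EV_NM = 1239.84193  # photon energy (eV) * wavelength (nm)

# Lorentz-Drude parameters (Rakic et al. 1998, Table 1): plasma energy (eV),
# then (oscillator strength f, damping Gamma eV, resonance omega eV) with the
# first row the free-electron (Drude) term at omega = 0.
LD_PARAMS = {
    "Cr": {
        "wp": 10.75,
        "osc": [
            (0.168, 0.047, 0.000),
            (0.151, 3.175, 0.121),
            (0.150, 1.305, 0.543),
            (1.149, 2.676, 1.970),
            (0.825, 1.335, 8.775),
        ],
    },
}


# Drude + two critical points, Au (Etchegoin et al. 2006, with the 2007 erratum):
# eps_inf, plasma wavelength (nm), Drude damping (nm), then per critical point
# (amplitude A, phase phi, resonance wavelength nm, broadening nm).
AU_DCP = {
    "eps_inf": 1.54,
    "lambda_p": 143.0,
    "gamma_p": 14500.0,
    "cp": [
        (1.27, -np.pi / 4, 470.0, 1900.0),
        (1.10, -np.pi / 4, 325.0, 1060.0),
    ],
}


def gold_epsilon(wavelength_nm: np.ndarray) -> np.ndarray:
    lam = np.asarray(wavelength_nm, dtype=float)
    p = AU_DCP
    eps = p["eps_inf"] - 1.0 / (
        p["lambda_p"] ** 2 * (1.0 / lam**2 + 1j / (p["gamma_p"] * lam))
    )
    for a, phi, lj, gj in p["cp"]:
        eps = eps + (a / lj) * (
            np.exp(1j * phi) / (1.0 / lj - 1.0 / lam - 1j / gj)
            + np.exp(-1j * phi) / (1.0 / lj + 1.0 / lam + 1j / gj)
        )
    return eps


def lorentz_drude_epsilon(material: str, wavelength_nm: np.ndarray) -> np.ndarray:
    p = LD_PARAMS[material]
    w = HC_EV_NM / np.asarray(wavelength_nm, dtype=float)  # eV
    f0, g0, _ = p["osc"][0]
    eps = 1 - f0 * p["wp"] ** 2 / (w * (w + 1j * g0))
    for f, g, wj in p["osc"][1:]:
        eps = eps + f * p["wp"] ** 2 / ((wj**2 - w**2) - 1j * w * g)
    return eps


PROVENANCE = {
    "Au": "Drude + two critical points, Etchegoin et al., J. Chem. Phys. 125, 164705 (2006)",
    "Cr": "Lorentz-Drude model, Rakic et al., Appl. Opt. 37, 5271 (1998)",
}


def main() -> None:
    outdir = Path(__file__).resolve().parents[1] / "src" / "tirekit" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    lam = np.arange(400.0, 1000.0 + 1e-9, 5.0)
    for material in ("Au", "Cr"):
        eps = gold_epsilon(lam) if material == "Au" else lorentz_drude_epsilon(material, lam)
        # n + i*kappa = sqrt(eps) with the root in the upper half plane
        nk = np.sqrt(eps)
        nk = np.where(nk.imag < 0, -nk, nk)
        path = outdir / f"{material.lower()}_nk.csv"
        with path.open("w") as fh:
            fh.write(f"# material = {material}\n")
            fh.write(f"# provenance = {PROVENANCE[material]}\n")
            fh.write("# generated_by = scripts/build_material_tables.py\n")
            fh.write("wavelength_nm,n,k\n")
            for L, v in zip(lam, nk):
                fh.write(f"{L:.1f},{v.real:.6f},{v.imag:.6f}\n")
        print(f"wrote {path} ({lam.size} rows)")


if __name__ == "__main__":
    main()
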