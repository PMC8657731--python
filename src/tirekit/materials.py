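"""Built-in material library for the default sensor stack.

BK7 glass uses the standard Schott three-term Sellmeier coefficients; the
aqueous buffer is modelled as water with a two-term Cauchy fit. Gold and
chromium come from packaged n,k tables (400-1000 nm, 5 nm step, linearly
interpolated) computed from the Lorentz-Drude compilation of Rakic et al.
(1998); see the provenance headers in ``tirekit/data`` and
``scripts/build_material_tables.py``. Any table in the same CSV format can
be swapped in via :func:`load_material_table`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .dispersion import Cauchy, Sellmeier, Tabulated

__all__ = ["bk7", "water", "gold", "chromium", "load_material_table", "MATERIALS"]


def bk7() -> Sellmeier:
    """Schott N-BK7 borosilicate glass (the coupling prism)."""
    return Sellmeier(
        b=(1.03961212, 0.231792344, 1.01046945),
        c=(0.00600069867, 0.0200179144, 103.560653),
    )


def water() -> Cauchy:
    """Aqueous buffer, visible-range Cauchy fit (n ~ 1.33)."""
    return Cauchy(a=1.3230, b=0.00322)


def load_material_table(path: str | Path, name: str | None = None) -> Tabulated:
    """Read a ``wavelength_nm,n,k`` CSV (``#`` comment header allowed)."""
    path = Path(path)
    rows = np.loadtxt(path, delimiter=",", comments="#", skiprows=_header_rows(path))
    rows = np.atleast_2d(rows)
    return Tabulated(
        wavelengths_nm=rows[:, 0], n=rows[:, 1], k=rows[:, 2], name=name or path.stem
    )


def _header_rows(path: Path) -> int:
    """Number of leading lines to skip: comments plus the column-header line."""
    count = 0
    with open(path) as fh:
        for line in fh:
            count += 1
            if not line.startswith("#"):
                if line.strip() != "wavelength_nm,n,k":
                    raise ValueError(
                        f"{path}: expected column header 'wavelength_nm,n,k', got {line.strip()!r}"
                    )
                return count
    raise ValueError(f"{path}: no column header found")


@lru_cache(maxsize=None)
def _packaged_table(stem: str) -> Tabulated:
    ref = resources.files("tirekit.data").joinpath(f"{stem}_nk.csv")
    with resources.as_file(ref) as path:
        return load_material_table(path, name=stem)


def gold() -> Tabulated:
    """Thin-film gold n,k (packaged table, 400-1000 nm)."""
    return _packaged_table("au")


def chromium() -> Tabulated:
    """Chromium adhesion-layer n,k (packaged table, 400-1000 nm)."""
    return _packaged_table("cr")


MATERIALS = {
    "bk7": bk7,
    "water": water,
    "buffer": water,
    "au": gold,
    "gold": gold,
    "cr": chromium,
    "chromium": chromium,
}
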