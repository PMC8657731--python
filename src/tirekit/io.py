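"""Readers and writers for the package's plain-text formats.

Two CSV dialects carry the measurements:

* spectrum v1 — ``#`` comment lines with ``key = value`` metadata, then the
  exact column header ``wavelength_nm,psi_deg,delta_deg`` and numeric rows;
* trace v1 — same header style with ``concentration_M`` and
  ``wavelength_nm`` metadata, then ``time_s,psi_deg`` rows.

Both use '.' decimals, no thousands separators, and round-trip losslessly
at 9 significant digits. Stack and generator configurations are YAML
documents validated with explicit, field-naming error messages.
Concentrations are always S.I. molar in files; nanomolar formatting is for
logs and reports only.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml

from . import materials
from .binding import BindingModelParams
from .dispersion import Cauchy, DispersionModel, Sellmeier
from .kinetics import KineticTrace
from .optics import Layer, OpticalStack, TIRESpectrum
from .synthetic import GeneratorConfig, NoiseSpec

__all__ = [
    "ParseError",
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "load_stack_config",
    "load_generator_config",
    "sha256_of",
]

SPECTRUM_COLUMNS = "wavelength_nm,psi_deg,delta_deg"
TRACE_COLUMNS = "time_s,psi_deg"
_FLOAT_FMT = "%.9g"


class ParseError(ValueError):
    """A malformed file; the message carries file name and line number."""

    def __init__(self, path, line_no: int | None, message: str):
        loc = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _read_table(path, expected_columns: str, n_cols: int):
    """Shared parser for both dialects: metadata dict + numeric columns."""
    metadata: dict = {}
    rows: list[list[float]] = []
    header_seen = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise ParseError(path, line_no, "comment after the column header")
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(path, line_no, f"metadata line without '=': {body!r}")
                key, _, value = body.partition("=")
                try:
                    metadata[key.strip()] = float(value.strip())
                except ValueError:
                    metadata[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line != expected_columns:
                    raise ParseError(
                        path, line_no, f"expected column header {expected_columns!r}, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != n_cols:
                raise ParseError(path, line_no, f"expected {n_cols} columns, got {len(parts)}")
            try:
                rows.append(([float(p) for p in parts], line_no))
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric value: {exc}") from None
    if not header_seen:
        raise ParseError(path, None, "missing column header")
    if not rows:
        raise ParseError(path, None, "empty data section")
    return metadata, rows


def read_spectrum(path) -> TIRESpectrum:
    """Read a spectrum v1 CSV into a :class:`TIRESpectrum` (metadata preserved)."""
    metadata, rows = _read_table(path, SPECTRUM_COLUMNS, 3)
    values = np.array([r[0] for r in rows], dtype=float)
    w = values[:, 0]
    bad = np.nonzero(np.diff(w) <= 0)[0]
    if bad.size:
        line_no = rows[int(bad[0]) + 1][1]
        raise ParseError(path, line_no, "wavelengths not strictly increasing at this row")
    return TIRESpectrum(wavelengths=w, psi=values[:, 1], delta=values[:, 2], metadata=metadata)


def write_spectrum(spectrum: TIRESpectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, value in sorted(spectrum.metadata.items()):
            v = _FLOAT_FMT % value if isinstance(value, float) else value
            fh.write(f"# {key} = {v}\n")
        fh.write(SPECTRUM_COLUMNS + "\n")
        for w, p, d in zip(spectrum.wavelengths, spectrum.psi, spectrum.delta):
            fh.write(f"{_FLOAT_FMT % w},{_FLOAT_FMT % p},{_FLOAT_FMT % d}\n")


def read_trace(path) -> KineticTrace:
    """Read a trace v1 CSV into a :class:`KineticTrace`."""
    metadata, rows = _read_table(path, TRACE_COLUMNS, 2)
    if "concentration_M" not in metadata:
        raise ParseError(path, None, "missing required metadata 'concentration_M'")
    values = np.array([r[0] for r in rows], dtype=float)
    t = values[:, 0]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(path, rows[int(bad[0]) + 1][1], "times not strictly increasing")
    return KineticTrace(
        times=t,
        psi=values[:, 1],
        concentration_m=float(metadata["concentration_M"]),
        wavelength_nm=float(metadata.get("wavelength_nm", 700.0)),
        metadata=metadata,
    )


def write_trace(trace: KineticTrace, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata = dict(trace.metadata)
    metadata.setdefault("concentration_M", trace.concentration_m)
    metadata.setdefault("wavelength_nm", trace.wavelength_nm)
    with path.open("w") as fh:
        for key, value in sorted(metadata.items()):
            v = _FLOAT_FMT % value if isinstance(value, float) else value
            fh.write(f"# {key} = {v}\n")
        fh.write(TRACE_COLUMNS + "\n")
        for t, p in zip(trace.times, trace.psi):
            fh.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % p}\n")


# ---------------------------------------------------------------------------
# configuration documents


def _config_error(path, where: str, message: str) -> ValueError:
    return ValueError(f"{path}: {where}: {message}")


def _parse_dispersion(spec, path, where: str) -> DispersionModel:
    if isinstance(spec, str):
        key = spec.lower()
        if key not in materials.MATERIALS:
            raise _config_error(
                path, where, f"unknown material {spec!r}; choose from {sorted(materials.MATERIALS)}"
            )
        return materials.MATERIALS[key]()
    if not isinstance(spec, dict) or len(spec) != 1:
        raise _config_error(
            path, where, "dispersion must be a material name or a single-key mapping "
            "(cauchy / sellmeier / table)"
        )
    kind, body = next(iter(spec.items()))
    if kind == "cauchy":
        try:
            return Cauchy(
                a=float(body["a"]),
                b=float(body.get("b", 0.0)),
                c=float(body.get("c", 0.0)),
                k=float(body.get("k", 0.0)),
            )
        except KeyError as exc:
            raise _config_error(path, where, f"cauchy requires field {exc}") from None
    if kind == "sellmeier":
        try:
            return Sellmeier(b=tuple(map(float, body["b"])), c=tuple(map(float, body["c"])))
        except (KeyError, TypeError) as exc:
            raise _config_error(path, where, f"sellmeier requires 3-element 'b' and 'c': {exc}")
    if kind == "table":
        return materials.load_material_table(Path(path).parent / body)
    raise _config_error(path, where, f"unknown dispersion kind {kind!r}")


def load_stack_config(path) -> OpticalStack:
    """Build an :class:`OpticalStack` from a YAML stack definition.

    Required fields: ``incidence_medium``, ``exit_medium``, ``layers`` (each
    with ``name``, ``thickness_nm`` and a material/dispersion), ``angle_deg``
    and a ``wavelengths`` block with ``min_nm``/``max_nm``/``step_nm``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise _config_error(path, "document", "top level must be a mapping")
    for required in ("incidence_medium", "exit_medium", "layers", "wavelengths"):
        if required not in doc:
            raise _config_error(path, "document", f"missing required field {required!r}")
    wl = doc["wavelengths"]
    for required in ("min_nm", "max_nm", "step_nm"):
        if required not in wl:
            raise _config_error(path, "wavelengths", f"missing field {required!r}")
    grid = np.arange(float(wl["min_nm"]), float(wl["max_nm"]) + 1e-9, float(wl["step_nm"]))
    layers = []
    for i, entry in enumerate(doc["layers"]):
        where = f"layers[{i}]"
        for required in ("name", "thickness_nm"):
            if required not in entry:
                raise _config_error(path, where, f"missing field {required!r}")
        disp_spec = entry.get("dispersion", entry.get("material"))
        if disp_spec is None:
            raise _config_error(path, where, "needs 'material' or 'dispersion'")
        layers.append(
            Layer(
                name=str(entry["name"]),
                thickness_nm=float(entry["thickness_nm"]),
                dispersion=_parse_dispersion(disp_spec, path, where),
            )
        )
    return OpticalStack(
        incidence_medium=_parse_dispersion(doc["incidence_medium"], path, "incidence_medium"),
        layers=tuple(layers),
        exit_medium=_parse_dispersion(doc["exit_medium"], path, "exit_medium"),
        angle_deg=float(doc.get("angle_deg", 68.0)),
        wavelength_grid=grid,
    )


def load_generator_config(path, seed: int | None = None) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from YAML; ``seed`` overrides the file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise _config_error(path, "document", "top level must be a mapping")
    kwargs: dict = {}
    if "stack" in doc:
        stack_path = Path(path).parent / doc["stack"]
        kwargs["stack"] = load_stack_config(stack_path)
    if "binding" in doc:
        try:
            kwargs["binding"] = BindingModelParams(**{k: float(v) for k, v in doc["binding"].items()})
        except TypeError as exc:
            raise _config_error(path, "binding", str(exc)) from None
    for key in ("ka", "kd", "trace_wavelength_nm", "trace_interval_s",
                "trace_tau_multiple", "trace_min_duration_s", "ns_tau_factor"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "concentrations_m" in doc:
        kwargs["concentrations_m"] = tuple(float(c) for c in doc["concentrations_m"])
    noise_doc = dict(doc.get("noise", {}))
    if seed is not None:
        noise_doc["seed"] = int(seed)
    if noise_doc:
        try:
            kwargs["noise"] = NoiseSpec(**noise_doc)
        except TypeError as exc:
            raise _config_error(path, "noise", str(exc)) from None
    try:
        return GeneratorConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise _config_error(path, "generator", str(exc)) from None


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
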