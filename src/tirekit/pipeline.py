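"""End-to-end driver: dataset generation, calibration, fits, affinity, manifest.

``run_pipeline`` consumes a directory of spectrum/trace CSVs (typically
written by :func:`generate_dataset`) and executes the full analysis chain:

    calibrate metals  ->  biolayer thickness per concentration
                      ->  exponential tau per sensorgram
                      ->  1/tau vs C regression -> ka, kd, K_D

Results are written as plain CSV plus a JSON run manifest (tool version,
input checksums, seed, timestamps) from which the run can be reproduced
byte-identically. Any stage failure raises :class:`PipelineStageError`
tagged with the stage name.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .fitting import DEFAULT_WEIGHTS, calibrate_metal, thickness_series
from .io import read_spectrum, read_trace, sha256_of, write_spectrum, write_trace
from .kinetics import estimate_affinity, fit_exponential
from .optics import OpticalStack, default_stack
from .synthetic import GeneratorConfig, generate_bare, generate_titration, generate_trace

__all__ = ["RunManifest", "PipelineStageError", "generate_dataset", "run_pipeline"]

logger = logging.getLogger("tirekit")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record: with the same inputs and package version,
    the run regenerates every output byte-identically."""

    tool_version: str
    config_hash: str
    inputs: dict  # path -> sha256
    outputs: dict  # path -> sha256
    seed: int | None
    started_utc: str
    finished_utc: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def generate_dataset(config: GeneratorConfig, outdir) -> list[Path]:
    """Emit a complete synthetic experiment into ``outdir``.

    Writes ``bare.csv`` (metal-only spectrum for calibration),
    ``spectrum_NN.csv`` for the C=0 baseline and each titration
    concentration, and ``trace_NN.csv`` per kinetic concentration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    bare = generate_bare(config)
    path = outdir / "bare.csv"
    write_spectrum(bare, path)
    written.append(path)

    for i, (c, spectrum) in enumerate(generate_titration(config)):
        path = outdir / f"spectrum_{i:02d}.csv"
        write_spectrum(spectrum, path)
        written.append(path)

    for i, c in enumerate(config.concentrations_m):
        trace = generate_trace(config, c)
        path = outdir / f"trace_{i:02d}.csv"
        write_trace(trace, path)
        written.append(path)
    return written


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def run_pipeline(
    indir,
    outdir,
    template: OpticalStack | None = None,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    seed: int | None = None,
) -> RunManifest:
    """Run calibration, thickness series and affinity analysis on a dataset.

    ``indir`` must hold spectrum v1 / trace v1 CSVs following the
    ``bare.csv`` / ``spectrum_*.csv`` / ``trace_*.csv`` naming convention.
    Writes ``thickness.csv``, ``affinity.csv`` and ``manifest.json`` into
    ``outdir`` and returns the manifest.
    """
    started = _utcnow()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = template or default_stack()

    spectrum_paths = sorted(indir.glob("spectrum_*.csv"))
    trace_paths = sorted(indir.glob("trace_*.csv"))
    bare_path = indir / "bare.csv"
    inputs = {
        str(p): sha256_of(p)
        for p in ([bare_path] if bare_path.exists() else []) + spectrum_paths + trace_paths
    }
    if not spectrum_paths and not trace_paths:
        raise PipelineStageError("inputs", f"no spectrum_*.csv or trace_*.csv files in {indir}")

    # --- stage 1: metal calibration -------------------------------------
    calibrated = template
    if bare_path.exists():
        try:
            calibrated = calibrate_metal(read_spectrum(bare_path), template, weights=weights)
        except Exception as exc:
            raise PipelineStageError("calibrate", str(exc)) from exc
        fitted = {l.name: l.thickness_nm for l in calibrated.layers}
        logger.info("calibrated metal thicknesses: %s", fitted)
    else:
        logger.info("no bare.csv found; using template metal thicknesses")

    outputs: dict = {}

    # --- stage 2: thickness series ---------------------------------------
    if spectrum_paths:
        try:
            tagged = []
            for p in spectrum_paths:
                s = read_spectrum(p)
                if "concentration_M" not in s.metadata:
                    raise ValueError(f"{p}: spectrum lacks 'concentration_M' metadata")
                tagged.append((float(s.metadata["concentration_M"]), s))
            series = thickness_series(tagged, calibrated, weights=weights)
        except Exception as exc:
            raise PipelineStageError("thickness_series", str(exc)) from exc
        thickness_path = outdir / "thickness.csv"
        table = series.table.rename(columns={"concentration_m": "concentration_M"})
        table.to_csv(thickness_path, index=False, float_format="%.9g")
        outputs[str(thickness_path)] = sha256_of(thickness_path)
        logger.info("thickness series:\n%s", table)

    # --- stage 3: kinetics -> affinity -----------------------------------
    if trace_paths:
        try:
            fits = []
            for p in trace_paths:
                trace = read_trace(p)
                fits.append((trace.concentration_m, fit_exponential(trace)))
            affinity = estimate_affinity(fits)
        except Exception as exc:
            raise PipelineStageError("fit_kinetics", str(exc)) from exc
        affinity_path = outdir / "affinity.csv"
        with affinity_path.open("w") as fh:
            fh.write("C_M,tau_s,tau_se_s\n")
            for c, f in sorted(fits, key=lambda cf: cf[0]):
                fh.write(f"{c:.9g},{f.tau_s:.9g},{f.tau_se_s:.9g}\n")
            fh.write("# ka,kd,KD,KD_se,R2\n")
            fh.write(
                f"# {affinity.ka:.9g},{affinity.kd:.9g},{affinity.KD:.9g},"
                f"{affinity.KD_se:.9g},{affinity.r_squared:.9g}\n"
            )
        outputs[str(affinity_path)] = sha256_of(affinity_path)
        logger.info(
            "affinity: ka=%.4g M^-1 s^-1, kd=%.4g s^-1, KD=%.4g M (%.3g nM)",
            affinity.ka, affinity.kd, affinity.KD, affinity.KD * 1e9,
        )

    config_hash = hashlib.sha256(
        repr((sorted(inputs.items()), weights, template.angle_deg)).encode()
    ).hexdigest()
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config_hash,
        inputs=inputs,
        outputs=outputs,
        seed=seed,
        started_utc=started,
        finished_utc=_utcnow(),
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
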