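"""Reproducible analysis pipeline: config schema, stage runners, reports.

Ties the stages together behind one validated configuration object so a
run is replayable from the artifacts it writes. Each runner writes into an
output directory:

* a ``config.yaml`` echo sufficient to replay the run exactly,
* CSV/JSON reports (comma-separated, '.' decimal, header row, UTF-8, no
  index column; JSON with sorted keys), and
* a deterministic ``run_log.txt`` recording the seed, config hash, package
  version and characteristic-equation residuals of reported eigenvalues.

There is no shell entry point: these functions plus the ``examples/``
scripts are the interface.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .beams import AirLoad, TaperedBeam
from .deflection import (
    LINEARITY_RATIO_THRESHOLD,
    deflection_profile,
    max_deflection,
)
from .modal import (
    amplitude_from_tip_force,
    characteristic_residual,
    solve_modes,
)
from .synthetic import FeatherGeometry, GeneratorConfig, generate_feather, summarize_feather
from .vibration import (
    DEFAULT_SAMPLES_PER_PERIOD,
    VibrationField,
    tip_kinematics,
    tip_timeseries,
)

__all__ = [
    "BeamBlock",
    "LoadBlock",
    "ExcitationBlock",
    "RunConfig",
    "load_config",
    "run_modes",
    "run_deflect",
    "run_vibrate",
    "run_generate",
    "run_analyze",
]


class BeamBlock(BaseModel):
    """Single-beam geometry and material (SI units)."""

    model_config = ConfigDict(frozen=True)

    length_l: float = Field(gt=0, description="beam length [m]")
    root_thickness_t: float = Field(gt=0, description="thickness at the clamped root [m]")
    width_w: float = Field(gt=0, description="beam width [m]")
    young_E: float = Field(gt=0, description="Young's modulus [Pa]")
    density_rho: float = Field(gt=0, description="mass density [kg/m^3]")

    def tapered(self) -> TaperedBeam:
        return TaperedBeam(
            length_l=self.length_l,
            root_thickness_t=self.root_thickness_t,
            width_w=self.width_w,
            young_E=self.young_E,
        )

    def uniform(self):
        return self.tapered().root_section(self.density_rho)


class LoadBlock(BaseModel):
    """Distributed air-load parameters: q = m g / A."""

    model_config = ConfigDict(frozen=True)

    bird_mass_m: float = Field(gt=0, description="bird mass [kg]")
    gravity_g: float = Field(default=9.81, gt=0, description="gravitational acceleration [m/s^2]")
    wing_body_area_A: float = Field(gt=0, description="wing + body area [m^2]")

    def air_load(self) -> AirLoad:
        return AirLoad(
            bird_mass_m=self.bird_mass_m,
            gravity_g=self.gravity_g,
            wing_body_area_A=self.wing_body_area_A,
        )


class ExcitationBlock(BaseModel):
    """Tip-force excitation released from rest (phase pi/2 by default)."""

    model_config = ConfigDict(frozen=True)

    tip_force_F: float = Field(ge=0, description="released tip force [N]")
    phase_phi: float = Field(default=math.pi / 2.0, description="phase angle [rad]")


class RunConfig(BaseModel):
    """Full run configuration; any stage uses only the blocks it needs."""

    model_config = ConfigDict(frozen=True)

    beam: Optional[BeamBlock] = None
    load: Optional[LoadBlock] = None
    excitation: Optional[ExcitationBlock] = None
    generator: Optional[GeneratorConfig] = None
    n_modes: int = Field(default=6, ge=1)
    seed: Optional[int] = Field(default=None, description="overrides generator.seed when set")
    formats: tuple[str, ...] = ("csv", "json")
    samples_per_period: int = Field(default=DEFAULT_SAMPLES_PER_PERIOD, ge=2)

    def config_echo(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _require(block, name: str):
    if block is None:
        raise ValueError(f"config validation error: required block '{name}' is missing")
    return block


def _prepare(out_dir: str | Path, config: RunConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.config_echo(), encoding="utf-8")
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def _write_table(out: Path, stem: str, df: pd.DataFrame, formats: tuple[str, ...]) -> None:
    if "csv" in formats:
        df.to_csv(out / f"{stem}.csv", index=False)
    if "json" in formats:
        _write_json(out / f"{stem}.json", {"rows": df.to_dict(orient="records")})


def run_modes(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Solve the cantilever modes of the configured beam and write the table.

    Emits ``modes.csv``/``modes.json`` with columns ``mode_index``, ``beta``,
    ``wavenumber_k``, ``sigma``, ``omega_p``, plus the config echo and a log
    carrying the characteristic-equation residual of every eigenvalue.
    """
    beam_block = _require(config.beam, "beam")
    out = _prepare(out_dir, config)
    modes = solve_modes(beam_block.uniform(), config.n_modes)
    df = pd.DataFrame(
        {
            "mode_index": [m.mode_index for m in modes],
            "beta": [m.beta for m in modes],
            "wavenumber_k": [m.wavenumber_k for m in modes],
            "sigma": [m.sigma for m in modes],
            "omega_p": [m.omega_p for m in modes],
        }
    )
    _write_table(out, "modes", df, config.formats)
    lines = [f"featherbeam {__version__}", f"n_modes {config.n_modes}"]
    lines += [
        f"mode {m.mode_index}: beta={m.beta!r} residual={characteristic_residual(m.beta):.3e}"
        for m in modes
    ]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return df


def run_deflect(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Static air-load deflection of the configured tapered beam.

    Writes the ``deflection.csv`` profile (x, shear, moment, inertia,
    deflection) and a ``deflection_summary.json`` with delta_max and the
    slenderness flag.
    """
    beam_block = _require(config.beam, "beam")
    load_block = _require(config.load, "load")
    out = _prepare(out_dir, config)
    beam = beam_block.tapered()
    load = load_block.air_load()
    df = deflection_profile(beam, load)
    _write_table(out, "deflection", df, config.formats)
    d_max = max_deflection(beam, load, warn=False)
    _write_json(
        out / "deflection_summary.json",
        {
            "delta_max": d_max,
            "delta_ratio": d_max / beam.length_l,
            "linearity_warning": d_max / beam.length_l > LINEARITY_RATIO_THRESHOLD,
            "pressure_q": load.pressure_q,
        },
    )
    return df


def run_vibrate(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """First-mode tip response of the configured beam under a released force.

    Writes a one-period ``vibration.csv`` time series (time,
    tip_displacement, tip_velocity, angular_velocity) and a
    ``kinematics.json`` with v_max, omega_max and the tip coefficient.
    """
    beam_block = _require(config.beam, "beam")
    exc_block = _require(config.excitation, "excitation")
    out = _prepare(out_dir, config)
    beam = beam_block.uniform()
    mode1 = solve_modes(beam, 1)[0]
    excitation = amplitude_from_tip_force(exc_block.tip_force_F, beam, exc_block.phase_phi)
    fld = VibrationField(beam=beam, mode=mode1, excitation=excitation)
    df = tip_timeseries(fld, samples_per_period=config.samples_per_period)
    _write_table(out, "vibration", df, config.formats)
    kin = tip_kinematics(fld)
    _write_json(
        out / "kinematics.json",
        {
            "v_max": kin.v_max,
            "omega_max": kin.omega_max,
            "coefficient": kin.coefficient,
            "amplitude_C": excitation.amplitude_C,
            "omega_p1": mode1.omega_p,
        },
    )
    return df


def _effective_generator(config: RunConfig) -> GeneratorConfig:
    gen = _require(config.generator, "generator")
    if config.seed is not None:
        gen = gen.model_copy(update={"seed": config.seed})
    return gen


def run_generate(config: RunConfig, out_dir: str | Path) -> FeatherGeometry:
    """Generate a synthetic feather and write its ``geometry.json``."""
    gen = _effective_generator(config)
    out = _prepare(out_dir, config)
    geometry = generate_feather(gen)
    (out / "geometry.json").write_text(geometry.to_json() + "\n", encoding="utf-8")
    return geometry


def run_analyze(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Full pipeline: generate a feather, run modal + static stages per barbule.

    Writes ``geometry.json``, the per-barbule ``summary.csv``, the config
    echo and a deterministic run log with seed, config hash, version and
    eigenvalue residuals. Byte-identical outputs for identical configs.
    """
    gen = _effective_generator(config)
    out = _prepare(out_dir, config)
    geometry = generate_feather(gen)
    (out / "geometry.json").write_text(geometry.to_json() + "\n", encoding="utf-8")
    summary = summarize_feather(geometry)
    summary.to_csv(out / "summary.csv", index=False)
    beta1 = solve_modes(geometry.barbs[0].barbules[0].section, 1)[0].beta if geometry.barbs else None
    lines = [
        f"featherbeam {__version__}",
        f"seed {gen.seed}",
        f"config_hash {gen.config_hash()}",
        f"n_barbs {len(geometry.barbs)}",
        f"n_barbules {geometry.n_barbules}",
    ]
    if beta1 is not None:
        lines.append(f"beta1 {beta1!r} residual {characteristic_residual(beta1):.3e}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return summary
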