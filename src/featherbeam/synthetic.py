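"""Seeded synthetic feather micro-geometry: rachis -> barbs -> barbules.

A contour feather is a hierarchy of cantilevers: barbs branch off the
rachis, and every barbule on a barb is itself a smaller cantilevered beam.
Real dimensions come from scanning electron microscopy; this module
generates stand-in geometries with user-configurable dimension
distributions so the modal and static models can be exercised end to end
without any imaging data.

Counts are drawn uniformly, dimensions log-uniformly (they are scale
parameters), from a seeded NumPy generator, so a feather is reproducible
bit-for-bit from ``(config, seed)``.

The shipped default ranges are documented placeholders chosen from
published feather-keratin and pigeon morphology values — they are NOT
measurements; every report echoes the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .beams import AirLoad, BeamSection, TaperedBeam
from .deflection import LINEARITY_RATIO_THRESHOLD, deflection_tapered
from .modal import mode_shape, natural_frequency, solve_eigenvalues

__all__ = [
    "GeneratorConfig",
    "Barbule",
    "Barb",
    "FeatherGeometry",
    "generate_feather",
    "summarize_feather",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic feather generator.

    Dimension ranges are ``(low, high)`` intervals in SI units; counts are
    inclusive integer intervals. Defaults are placeholder values for a
    pigeon contour feather (keratin E ~ 2.5 GPa, rho ~ 1150 kg/m^3;
    barbules a few hundred micrometres long and micrometres thick; barbs
    tens of millimetres long) — plausible, but not measured data.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_barbs_range: tuple[int, int] = (10, 20)
    barbules_per_barb_range: tuple[int, int] = (15, 30)
    barb_length_range: tuple[float, float] = (15e-3, 30e-3)
    barb_thickness_range: tuple[float, float] = (150e-6, 300e-6)
    barbule_length_range: tuple[float, float] = (180e-6, 400e-6)
    barbule_thickness_range: tuple[float, float] = (3e-6, 6e-6)
    width_to_thickness_ratio: float = Field(default=2.0, gt=0)
    young_E: float = Field(default=2.5e9, gt=0)
    density_rho: float = Field(default=1150.0, gt=0)
    bird_mass_m: float = Field(default=0.35, gt=0)
    wing_body_area_A: float = Field(default=0.06, gt=0)
    gravity_g: float = Field(default=9.81, gt=0)

    @model_validator(mode="after")
    def _check_ranges(self) -> "GeneratorConfig":
        for name in (
            "n_barbs_range",
            "barbules_per_barb_range",
            "barb_length_range",
            "barb_thickness_range",
            "barbule_length_range",
            "barbule_thickness_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0:
                raise ValueError(f"{name}: lower bound must be positive, got {lo}")
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.barbule_length_range[1] > self.barb_length_range[0]:
            raise ValueError(
                "hierarchy ordering violated: barbule_length_range upper bound "
                f"({self.barbule_length_range[1]}) exceeds barb_length_range lower bound "
                f"({self.barb_length_range[0]})"
            )
        return self

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form — recorded in every output."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass(frozen=True)
class Barbule:
    """One barbule: tapered beam plus its derived uniform root section."""

    beam: TaperedBeam
    section: BeamSection


@dataclass(frozen=True)
class Barb:
    """One barb with its attached barbules."""

    beam: TaperedBeam
    barbules: tuple[Barbule, ...]


@dataclass(frozen=True)
class FeatherGeometry:
    """A generated feather: barbs with barbules, shared material, air load."""

    barbs: tuple[Barb, ...]
    young_E: float
    density_rho: float
    load: AirLoad
    seed: int
    config_hash: str
    schema_version: str = field(default=SCHEMA_VERSION)

    @property
    def n_barbules(self) -> int:
        return sum(len(b.barbules) for b in self.barbs)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "material": {"young_E": self.young_E, "density_rho": self.density_rho},
            "load": {
                "bird_mass_m": self.load.bird_mass_m,
                "gravity_g": self.load.gravity_g,
                "wing_body_area_A": self.load.wing_body_area_A,
                "pressure_q": self.load.pressure_q,
            },
            "barbs": [
                {
                    "length_l": barb.beam.length_l,
                    "root_thickness_t": barb.beam.root_thickness_t,
                    "width_w": barb.beam.width_w,
                    "barbules": [
                        {
                            "length_l": bl.beam.length_l,
                            "root_thickness_t": bl.beam.root_thickness_t,
                            "width_w": bl.beam.width_w,
                            "section_area": bl.section.section_area,
                            "inertia_Iz": bl.section.inertia_Iz,
                        }
                        for bl in barb.barbules
                    ],
                }
                for barb in self.barbs
            ],
        }

    def to_json(self) -> str:
        """Deterministic JSON serialisation (sorted keys, fixed indent)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    # log-uniform; degenerate lo == hi collapses to the bound exactly
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _int_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_feather(config: GeneratorConfig) -> FeatherGeometry:
    """Sample a feather geometry from ``config``; reproducible from its seed.

    Counts are uniform integers on their inclusive ranges; lengths and
    thicknesses are log-uniform on theirs. Each barbule's uniform
    :class:`~featherbeam.beams.BeamSection` (area ``w t``, inertia
    ``w t^3/12`` at the root) is derived for modal analysis. Width is
    ``width_to_thickness_ratio`` times the local root thickness.
    """
    rng = np.random.default_rng(config.seed)
    ratio = config.width_to_thickness_ratio
    barbs = []
    for _ in range(_int_uniform(rng, *config.n_barbs_range)):
        barb_l = _log_uniform(rng, *config.barb_length_range)
        barb_t = _log_uniform(rng, *config.barb_thickness_range)
        barb_beam = TaperedBeam(
            length_l=barb_l,
            root_thickness_t=barb_t,
            width_w=ratio * barb_t,
            young_E=config.young_E,
        )
        barbules = []
        for _ in range(_int_uniform(rng, *config.barbules_per_barb_range)):
            bl_l = _log_uniform(rng, *config.barbule_length_range)
            bl_t = _log_uniform(rng, *config.barbule_thickness_range)
            beam = TaperedBeam(
                length_l=bl_l,
                root_thickness_t=bl_t,
                width_w=ratio * bl_t,
                young_E=config.young_E,
            )
            barbules.append(Barbule(beam=beam, section=beam.root_section(config.density_rho)))
        barbs.append(Barb(beam=barb_beam, barbules=tuple(barbules)))
    load = AirLoad(
        bird_mass_m=config.bird_mass_m,
        gravity_g=config.gravity_g,
        wing_body_area_A=config.wing_body_area_A,
    )
    return FeatherGeometry(
        barbs=tuple(barbs),
        young_E=config.young_E,
        density_rho=config.density_rho,
        load=load,
        seed=config.seed,
        config_hash=config.config_hash(),
    )


_SUMMARY_COLUMNS = [
    "barb_index",
    "barbule_index",
    "length_l",
    "root_thickness_t",
    "width_w",
    "omega1",
    "frequency1_hz",
    "vmax_per_amplitude",
    "delta_max",
    "delta_ratio",
    "linearity_warning",
]


def summarize_feather(geometry: FeatherGeometry) -> pd.DataFrame:
    """Per-barbule summary of the modal and static models.

    One row per barbule, ordered by (barb index, barbule index), with its
    root geometry, first natural angular frequency ``omega1`` [rad/s] and
    frequency in Hz, peak tip speed per unit modal amplitude
    ``vmax_per_amplitude`` [1/s], air-load tip deflection ``delta_max`` [m],
    the slenderness ratio ``delta_max / l``, and a flag marking rows where
    that ratio strains the linear theory.
    """
    beta1 = solve_eigenvalues(1)[0]
    tip_shape = mode_shape(beta1, 1.0)
    rows = []
    for bi, barb in enumerate(geometry.barbs):
        for ji, barbule in enumerate(barb.barbules):
            sec = barbule.section
            omega1 = natural_frequency(beta1, sec)
            vmax_per_c = beta1**2 * tip_shape / sec.length_l**2 * np.sqrt(sec.stiffness_ratio)
            d_max = deflection_tapered(barbule.beam, geometry.load, barbule.beam.length_l)
            ratio = d_max / barbule.beam.length_l
            rows.append(
                {
                    "barb_index": bi,
                    "barbule_index": ji,
                    "length_l": barbule.beam.length_l,
                    "root_thickness_t": barbule.beam.root_thickness_t,
                    "width_w": barbule.beam.width_w,
                    "omega1": omega1,
                    "frequency1_hz": omega1 / (2.0 * np.pi),
                    "vmax_per_amplitude": float(vmax_per_c),
                    "delta_max": d_max,
                    "delta_ratio": ratio,
                    "linearity_warning": bool(ratio > LINEARITY_RATIO_THRESHOLD),
                }
            )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
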