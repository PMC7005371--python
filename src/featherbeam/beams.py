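"""Geometric and material primitives for feather beam mechanics.

Barbules and barbs are modelled as keratin cantilever beams. Two geometric
idealisations coexist in the model family:

* a **uniform** rectangular cantilever (:class:`BeamSection`), used by the
  vibration eigenproblem, and
* a **linearly tapered** rectangular cantilever (:class:`TaperedBeam`) whose
  thickness falls from ``root_thickness_t`` at the clamped root to zero at
  the free tip, used by the static-deflection model.

The distributed aerodynamic load transmitted to the vane is represented by
:class:`AirLoad`, a pressure ``q = m g / A`` built from the bird's mass and
its wing-plus-body area.

All quantities are SI. Unit conversions (micrometres, milligrams, ...)
belong at the configuration boundary, never inside these types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BeamSection",
    "TaperedBeam",
    "AirLoad",
    "rectangular_section",
]


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value) or value <= 0.0:
            raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


@dataclass(frozen=True)
class BeamSection:
    """Uniform rectangular cantilever: geometry plus material.

    Parameters
    ----------
    length_l : float
        Beam length ``l`` [m].
    young_E : float
        Young's modulus ``E`` [Pa].
    density_rho : float
        Mass density ``rho`` [kg/m^3].
    section_area : float
        Cross-sectional area ``A`` [m^2].
    inertia_Iz : float
        Second moment of area about the bending axis ``I_z`` [m^4].
    """

    length_l: float
    young_E: float
    density_rho: float
    section_area: float
    inertia_Iz: float

    def __post_init__(self) -> None:
        _require_positive(
            length_l=self.length_l,
            young_E=self.young_E,
            density_rho=self.density_rho,
            section_area=self.section_area,
            inertia_Iz=self.inertia_Iz,
        )
        if not math.isfinite(self.stiffness_ratio) or self.stiffness_ratio <= 0.0:
            raise ValueError("E*Iz/(rho*A) must be finite and positive")

    @property
    def stiffness_ratio(self) -> float:
        """``E I_z / (rho A)`` [m^4/s^2] — the wave-stiffness parameter."""
        return (self.young_E * self.inertia_Iz) / (self.density_rho * self.section_area)


def rectangular_section(
    length_l: float,
    thickness_t: float,
    width_w: float,
    young_E: float,
    density_rho: float,
) -> BeamSection:
    """Build a uniform :class:`BeamSection` from rectangular dimensions.

    Area is ``w t`` and the second moment about the bending axis is
    ``w t^3 / 12`` (bending across the thickness).
    """
    _require_positive(thickness_t=thickness_t, width_w=width_w)
    return BeamSection(
        length_l=length_l,
        young_E=young_E,
        density_rho=density_rho,
        section_area=width_w * thickness_t,
        inertia_Iz=width_w * thickness_t**3 / 12.0,
    )


@dataclass(frozen=True)
class TaperedBeam:
    """Linearly tapered rectangular cantilever (barbule or barb).

    Thickness decreases linearly from ``root_thickness_t`` at the clamped
    root (x = 0) to zero at the free tip (x = l); the width ``width_w`` is
    constant. The taper slope ``k = t/l`` is derived, not stored.
    """

    length_l: float
    root_thickness_t: float
    width_w: float
    young_E: float

    def __post_init__(self) -> None:
        _require_positive(
            length_l=self.length_l,
            root_thickness_t=self.root_thickness_t,
            width_w=self.width_w,
            young_E=self.young_E,
        )

    @property
    def taper_slope(self) -> float:
        """Thickness decrease per unit length, ``k = t / l`` (dimensionless)."""
        return self.root_thickness_t / self.length_l

    def thickness(self, x: float) -> float:
        """Local thickness ``t - k x`` [m] at position ``x`` in ``[0, l]``."""
        self._check_domain(x, include_tip=True)
        return self.root_thickness_t - self.taper_slope * x

    def _check_domain(self, x: float, include_tip: bool) -> None:
        hi = self.length_l
        if not (0.0 <= x <= hi) or (not include_tip and x == hi):
            raise ValueError(f"x={x!r} outside the beam domain [0, {hi}{']' if include_tip else ')'}")

    def root_section(self, density_rho: float) -> BeamSection:
        """Uniform :class:`BeamSection` using the root dimensions.

        The vibration model assumes a uniform beam; tapered barbules enter
        it through their root thickness and width. This is an idealisation:
        taper is ignored by the modal model.
        """
        return rectangular_section(
            length_l=self.length_l,
            thickness_t=self.root_thickness_t,
            width_w=self.width_w,
            young_E=self.young_E,
            density_rho=density_rho,
        )


@dataclass(frozen=True)
class AirLoad:
    """Distributed air pressure on the vane, ``q = m g / A``.

    Parameters
    ----------
    bird_mass_m : float
        Total mass of the bird ``m`` [kg].
    gravity_g : float
        Gravitational acceleration ``g`` [m/s^2].
    wing_body_area_A : float
        Combined wing and body planform area ``A`` [m^2]. Distinct from a
        beam's cross-sectional area.
    """

    bird_mass_m: float
    gravity_g: float
    wing_body_area_A: float

    def __post_init__(self) -> None:
        _require_positive(
            bird_mass_m=self.bird_mass_m,
            gravity_g=self.gravity_g,
            wing_body_area_A=self.wing_body_area_A,
        )

    @property
    def pressure_q(self) -> float:
        """Load density ``q = m g / A`` [Pa]."""
        return self.bird_mass_m * self.gravity_g / self.wing_body_area_A
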