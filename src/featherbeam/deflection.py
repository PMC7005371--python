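"""Static deflection of tapered barbules and barbs under load.

Under flight-generated air pressure the vane carries a distributed load of
density ``q = m g / A`` (bird mass over wing-plus-body area). For a
cantilevered, linearly tapered rectangular beam of width ``w``, root
thickness ``t`` and length ``l``:

    shear    Q(x) = q w (l - x)
    moment   M(x) = q w (l - x)^2 / 2
    inertia  I(x) = w (t - (t/l) x)^3 / 12

The deflection integral has integrand ``6 q (l - y)^3 / (E (t - (t/l) y)^3)``,
which cancels exactly to the constant ``6 q l^3 / (E t^3)`` because the
taper vanishes at the tip in proportion to the remaining span:
``t - (t/l) y = (t/l)(l - y)``. The deflection is therefore *linear* along
the beam,

    delta(x) = 6 q l^3 x / (E t^3),    delta_max = 6 m g l^4 / (E A t^3),

for barbules and, with ``l_B``/``t_B`` substituted, for barbs. A quadrature
mode integrates the uncancelled integrand as an independent check.

A point (combing) load ``P`` on a *uniform* cantilever gives the classic
tip deflection ``P l^3 / (3 E I_z)`` (unit-load/Castigliano integral of
``P (l - x)^2 / (E I_z)``), so the barb springs back elastically once the
comb releases it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .beams import AirLoad, BeamSection, TaperedBeam

__all__ = [
    "shear_and_moment",
    "section_inertia",
    "deflection_tapered",
    "deflection_barb",
    "point_load_deflection",
    "deflection_profile",
    "max_deflection",
    "LINEARITY_RATIO_THRESHOLD",
]

#: Slenderness guard: warn when delta_max / l exceeds this (small-deflection
#: theory loses credibility). Implementation choice, not a modelled bound.
LINEARITY_RATIO_THRESHOLD = 0.1


def _check_x(x: float, length: float, include_tip: bool = True) -> None:
    hi_ok = x <= length if include_tip else x < length
    if not (0.0 <= x and hi_ok):
        raise ValueError(f"x={x!r} outside beam domain [0, {length}{']' if include_tip else ')'}")


def shear_and_moment(beam: TaperedBeam, load: AirLoad, x: float) -> tuple[float, float]:
    """Internal shear force [N] and bending moment [N·m] at ``x``.

    ``Q(x) = q w (l - x)`` and ``M(x) = q w (l - x)^2 / 2``; both vanish at
    the free tip and satisfy ``dM/dx = -Q``.
    """
    _check_x(x, beam.length_l)
    span = beam.length_l - x
    line_load = load.pressure_q * beam.width_w
    return line_load * span, 0.5 * line_load * span**2


def section_inertia(beam: TaperedBeam, x: float) -> float:
    """Second moment of area ``I(x) = w (t - (t/l) x)^3 / 12`` [m^4].

    Zero at the tip where the taper closes; a warning (not an error) is
    emitted there because the deflection closed form stays finite.
    """
    _check_x(x, beam.length_l)
    if x == beam.length_l:
        warnings.warn(
            "section inertia is zero at the tapered tip (x = l)", RuntimeWarning, stacklevel=2
        )
        return 0.0
    local_t = beam.root_thickness_t - beam.taper_slope * x
    return beam.width_w * local_t**3 / 12.0


def deflection_tapered(
    beam: TaperedBeam, load: AirLoad, x: float, method: str = "closed"
) -> float:
    """Deflection ``delta(x) = 6 q l^3 x / (E t^3)`` [m] of a tapered cantilever.

    ``method='closed'`` evaluates the linear closed form;
    ``method='quadrature'`` integrates the uncancelled integrand
    ``6 q (l - y)^3 / (E (t - (t/l) y)^3)`` over ``[0, x]`` with adaptive
    quadrature. The two agree to round-off because the integrand is the
    constant ``6 q l^3 / (E t^3)`` after cancellation.
    """
    _check_x(x, beam.length_l)
    q = load.pressure_q
    E, t, l = beam.young_E, beam.root_thickness_t, beam.length_l
    if method == "closed":
        return 6.0 * q * l**3 * x / (E * t**3)
    if method == "quadrature":
        if x == 0.0:
            return 0.0
        k = beam.taper_slope

        def integrand(y: float) -> float:
            return 6.0 * q * (l - y) ** 3 / (E * (t - k * y) ** 3)

        value, _ = quad(integrand, 0.0, x, limit=200)
        return value
    raise ValueError(f"unknown method {method!r}; expected 'closed' or 'quadrature'")


def deflection_barb(barb: TaperedBeam, load: AirLoad, x: float, method: str = "closed") -> float:
    """Barb deflection ``6 m g l_B^3 x / (E A t_B^3)`` [m].

    The barb obeys the same tapered-cantilever closed form as the barbule
    with its own length ``l_B`` and root thickness ``t_B``.
    """
    return deflection_tapered(barb, load, x, method=method)


def max_deflection(beam: TaperedBeam, load: AirLoad, warn: bool = True) -> float:
    """Tip deflection ``delta_max = 6 m g l^4 / (E A t^3)`` [m].

    When ``warn`` is true, emits a ``RuntimeWarning`` if
    ``delta_max / l`` exceeds :data:`LINEARITY_RATIO_THRESHOLD`, flagging
    that the small-deflection assumption is strained.
    """
    d = deflection_tapered(beam, load, beam.length_l)
    if warn and d / beam.length_l > LINEARITY_RATIO_THRESHOLD:
        warnings.warn(
            f"delta_max/l = {d / beam.length_l:.3g} exceeds {LINEARITY_RATIO_THRESHOLD}; "
            "linear beam theory is questionable here",
            RuntimeWarning,
            stacklevel=2,
        )
    return d


def point_load_deflection(beam_uniform: BeamSection, P: float, method: str = "closed") -> float:
    """Tip deflection ``P l^3 / (3 E I_z)`` [m] of a uniform cantilever.

    The combing load case: a steady lateral tip force ``P``. The
    quadrature mode evaluates the unit-load integral
    ``int_0^l P (l - x)^2 / (E I_z) dx`` and agrees with the closed form to
    round-off.
    """
    if P < 0.0:
        raise ValueError(f"point load must be non-negative, got {P!r}")
    l, E, Iz = beam_uniform.length_l, beam_uniform.young_E, beam_uniform.inertia_Iz
    if method == "closed":
        return P * l**3 / (3.0 * E * Iz)
    if method == "quadrature":
        value, _ = quad(lambda x: P * (l - x) ** 2 / (E * Iz), 0.0, l, limit=200)
        return value
    raise ValueError(f"unknown method {method!r}; expected 'closed' or 'quadrature'")


def deflection_profile(beam: TaperedBeam, load: AirLoad, n_points: int = 101) -> pd.DataFrame:
    """Tabulate shear, moment, inertia and deflection along the beam.

    Returns a DataFrame with columns ``x``, ``shear``, ``moment``,
    ``inertia`` and ``deflection`` at ``n_points`` stations from root to
    tip. The tip row carries zero inertia (taper closes there).
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    xs = np.linspace(0.0, beam.length_l, n_points)
    line_load = load.pressure_q * beam.width_w
    span = beam.length_l - xs
    local_t = beam.root_thickness_t - beam.taper_slope * xs
    slope = 6.0 * load.pressure_q * beam.length_l**3 / (beam.young_E * beam.root_thickness_t**3)
    return pd.DataFrame(
        {
            "x": xs,
            "shear": line_load * span,
            "moment": 0.5 * line_load * span**2,
            "inertia": beam.width_w * local_t**3 / 12.0,
            "deflection": slope * xs,
        }
    )
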