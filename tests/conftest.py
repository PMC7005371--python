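"""Shared fixtures: reference eigenvalues and representative beams."""

import math

import pytest

from featherbeam import (
    AirLoad,
    GeneratorConfig,
    TaperedBeam,
    amplitude_from_tip_force,
    rectangular_section,
    solve_modes,
)
from featherbeam.vibration import VibrationField

# Published first six dimensionless roots of cos(b) = -sech(b) (clamped-free
# beam). The sixth is truncated in print: the true root 17.2787595321 rounds
# to 17.278760, so agreement is asserted as |beta - printed| < 1e-6.
TABLE_ROOTS = [1.875104, 4.694091, 7.854757, 10.995541, 14.137168, 17.278759]

def boundary_condition_residuals(beta, shape):
    """Finite-difference residuals of the four clamped-free conditions.

    Returns (Y(0), Y'(0), Y''(1), Y'''(1)) estimated with one-sided
    stencils (the shape is only defined on [0, 1]), each already divided
    by the mode's maximum amplitude times the matching power of beta, so
    every entry is a dimensionless relative residual. The step 5e-3/beta
    balances stencil truncation (grows with beta) against roundoff.
    """
    import numpy as np

    h = 5e-3 / beta
    f = shape
    scale = np.max(np.abs(f(np.linspace(0.0, 1.0, 2001))))
    # forward/backward weights, accuracy >= 3 (Vandermonde-derived)
    slope0 = (
        -25 / 12 * f(0.0) + 4 * f(h) - 3 * f(2 * h) + 4 / 3 * f(3 * h) - 1 / 4 * f(4 * h)
    ) / h
    d2_tip = (
        35 / 12 * f(1.0)
        - 26 / 3 * f(1 - h)
        + 19 / 2 * f(1 - 2 * h)
        - 14 / 3 * f(1 - 3 * h)
        + 11 / 12 * f(1 - 4 * h)
    ) / h**2
    d3_tip = (
        17 / 4 * f(1.0)
        - 71 / 4 * f(1 - h)
        + 59 / 2 * f(1 - 2 * h)
        - 49 / 2 * f(1 - 3 * h)
        + 41 / 4 * f(1 - 4 * h)
        - 7 / 4 * f(1 - 5 * h)
    ) / h**3
    return (
        abs(f(0.0)) / scale,
        abs(slope0) / (scale * beta),
        abs(d2_tip) / (scale * beta**2),
        abs(d3_tip) / (scale * beta**3),
    )


# Keratin-like barbule: 300 um long, 5 um thick, 10 um wide.
BARBULE_DIMS = dict(
    length_l=300e-6, thickness_t=5e-6, width_w=10e-6, young_E=2.5e9, density_rho=1150.0
)


@pytest.fixture(scope="session")
def barbule_section():
    return rectangular_section(**BARBULE_DIMS)


@pytest.fixture(scope="session")
def unit_beam():
    """Beam with E*Iz/(rho*A) = 1 and l = 1 so omega = beta**2."""
    return rectangular_section(
        length_l=1.0, thickness_t=math.sqrt(12.0), width_w=1.0, young_E=1.0, density_rho=1.0
    )


@pytest.fixture(scope="session")
def tapered_barbule():
    return TaperedBeam(length_l=300e-6, root_thickness_t=5e-6, width_w=10e-6, young_E=2.5e9)


@pytest.fixture(scope="session")
def pigeon_load():
    return AirLoad(bird_mass_m=0.35, gravity_g=9.81, wing_body_area_A=0.06)


@pytest.fixture(scope="session")
def first_mode_field(barbule_section):
    mode1 = solve_modes(barbule_section, 1)[0]
    excitation = amplitude_from_tip_force(1e-6, barbule_section)
    return VibrationField(beam=barbule_section, mode=mode1, excitation=excitation)


@pytest.fixture
def degenerate_config():
    """Generator config with collapsed ranges: every barbule identical."""
    return GeneratorConfig(
        seed=7,
        n_barbs_range=(2, 2),
        barbules_per_barb_range=(3, 3),
        barb_length_range=(20e-3, 20e-3),
        barb_thickness_range=(200e-6, 200e-6),
        barbule_length_range=(300e-6, 300e-6),
        barbule_thickness_range=(5e-6, 5e-6),
    )
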