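"""Free bending vibration of a clamped-free (cantilever) Euler-Bernoulli beam.

A barbule clamped at its base on the barb vibrates as a cantilever. With the
separation ansatz ``y(x, t) = Y(x) sin(p t + phi)`` the beam equation
reduces to ``Y'''' = k^4 Y`` with ``k^4 = rho A p^2 / (E I_z)``, and the
clamped-free boundary conditions (zero deflection and slope at the root,
zero moment and shear at the tip) admit nontrivial solutions only where

    cos(k l) = -sech(k l),

equivalently ``cos(beta) cosh(beta) = -1`` with ``beta = k l``. The roots
``beta_n`` approach ``(2n - 1) pi / 2`` exponentially fast, which provides
guaranteed brackets for a numerical root-finder: ``sech`` decays, so each
bracket around an odd multiple of ``pi/2`` contains exactly one root.

Each root carries a natural angular frequency

    p_n = (beta_n / l)^2 sqrt(E I_z / (rho A))

and a mode shape

    Y(x)/C = cosh(beta xi) - cos(beta xi) - sigma [sinh(beta xi) - sin(beta xi)],

with ``xi = x/l`` and ``sigma = (sinh beta - sin beta)/(cosh beta + cos beta)``.
All hyperbolic expressions here are written in overflow-safe exponential
forms so that arbitrarily high modes can be requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .beams import BeamSection

__all__ = [
    "ModeSolution",
    "ExcitationAmplitude",
    "characteristic_residual",
    "solve_eigenvalues",
    "sigma_coefficient",
    "mode_shape",
    "natural_frequency",
    "amplitude_from_tip_force",
    "solve_modes",
]

#: Half-width of the root bracket around (2j-1)*pi/2 for modes j >= 2.
_BRACKET_HALF_WIDTH = 0.5
#: Bracket for the first mode (the only root below pi).
_FIRST_BRACKET = (1.0, 3.0)


def _sech(beta: float) -> float:
    # 2 e^-b / (1 + e^-2b): decays for large b instead of overflowing cosh.
    e = math.exp(-beta)
    return 2.0 * e / (1.0 + e * e)


def characteristic_residual(beta: float) -> float:
    """Residual ``cos(beta) + sech(beta)`` of the cantilever frequency equation.

    Zero exactly at the dimensionless eigenvalues ``beta = k l``. Uses an
    exponential form of ``sech`` that never overflows, so the residual is
    well defined for arbitrarily large ``beta``.

    Raises
    ------
    ValueError
        If ``beta`` is negative.
    """
    if beta < 0.0:
        raise ValueError(f"beta must be non-negative, got {beta!r}")
    return math.cos(beta) + _sech(beta)


def solve_eigenvalues(n_modes: int, xtol: float = 1e-14) -> list[float]:
    """First ``n_modes`` positive roots of ``cos(beta) = -sech(beta)``.

    Root ``j`` is bracketed in ``[(2j-1) pi/2 - 0.5, (2j-1) pi/2 + 0.5]``
    (``[1, 3]`` for ``j = 1``, the only root below ``pi``) and refined by
    Brent's method. The ``sech`` decay guarantees exactly one sign change
    per bracket, so the solve is deterministic.

    Parameters
    ----------
    n_modes : int
        Number of modes requested, ``>= 1``.
    xtol : float
        Absolute tolerance on ``beta`` passed to the root-finder.

    Returns
    -------
    list of float
        Roots in strictly increasing order. Each satisfies
        ``|cos(beta) + sech(beta)| < 1e-12``.
    """
    if int(n_modes) != n_modes or n_modes < 1:
        raise ValueError(f"n_modes must be a positive integer, got {n_modes!r}")
    roots: list[float] = []
    for j in range(1, int(n_modes) + 1):
        if j == 1:
            lo, hi = _FIRST_BRACKET
        else:
            center = (2 * j - 1) * math.pi / 2.0
            lo, hi = center - _BRACKET_HALF_WIDTH, center + _BRACKET_HALF_WIDTH
        flo, fhi = characteristic_residual(lo), characteristic_residual(hi)
        if flo * fhi > 0.0:
            raise RuntimeError(
                f"bracketing failed for mode {j}: residual({lo})={flo}, residual({hi})={fhi}"
            )
        root = brentq(characteristic_residual, lo, hi, xtol=xtol, rtol=4 * np.finfo(float).eps)
        resid = characteristic_residual(root)
        if abs(resid) >= 1e-12:
            raise RuntimeError(f"mode {j} refinement stalled: beta={root}, residual={resid}")
        roots.append(root)
    return roots


def _sigma_parts(beta: float) -> tuple[float, float]:
    """Return ``(sigma, 1 - sigma)``, both computed without cancellation.

    Multiplying numerator and denominator of sigma by ``2 e^-beta`` gives

        sigma = (1 - e^-2b - 2 e^-b sin b) / (1 + e^-2b + 2 e^-b cos b)

    which is overflow-safe for any beta. ``1 - sigma`` is formed from
    ``(e^-b + cos b + sin b)`` directly so the large-beta cancellation in
    ``cosh - sinh`` never happens in floating point.
    """
    e = math.exp(-beta)
    den = 1.0 + e * e + 2.0 * e * math.cos(beta)
    sigma = (1.0 - e * e - 2.0 * e * math.sin(beta)) / den
    one_minus_sigma = 2.0 * e * (e + math.cos(beta) + math.sin(beta)) / den
    return sigma, one_minus_sigma


def sigma_coefficient(beta: float) -> float:
    """Mode-shape coefficient ``sigma = (sinh b - sin b) / (cosh b + cos b)``.

    Tends to 0 as ``beta -> 0`` and to 1 as ``beta -> inf``; equals
    0.7341 (4 d.p.) at the first cantilever eigenvalue.
    """
    if beta <= 0.0:
        if beta == 0.0:
            return 0.0
        raise ValueError(f"beta must be positive, got {beta!r}")
    return _sigma_parts(beta)[0]


def mode_shape(beta: float, xi):
    """Normalised cantilever mode shape ``Y(xi l) / C`` at ``xi = x/l``.

    Evaluates ``cosh(b xi) - cos(b xi) - sigma(b) [sinh(b xi) - sin(b xi)]``
    in the exponential-difference form

        (1 - sigma) e^z / 2 + (1 + sigma) e^-z / 2 - cos z + sigma sin z,

    ``z = beta xi``, with ``1 - sigma`` computed cancellation-free, so the
    shape stays accurate for every tabulated mode (valid while ``e^z`` is
    representable, i.e. modes into the hundreds).

    ``xi`` may be a scalar or array in ``[0, 1]``; values outside the beam
    raise ``ValueError``. The clamped root gives ``Y(0) = 0`` exactly and
    the first mode's free end evaluates to 2.000.
    """
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < 0.0) or np.any(xi_arr > 1.0):
        raise ValueError("xi must lie in [0, 1]")
    if beta <= 0.0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    sigma, one_minus_sigma = _sigma_parts(beta)
    z = beta * xi_arr
    shape = (
        0.5 * one_minus_sigma * np.exp(z)
        + 0.5 * (1.0 + sigma) * np.exp(-z)
        - np.cos(z)
        + sigma * np.sin(z)
    )
    return shape if shape.ndim else float(shape)


def natural_frequency(beta: float, beam: BeamSection) -> float:
    """Angular natural frequency ``p = (beta/l)^2 sqrt(E I_z / (rho A))`` [rad/s]."""
    if beta <= 0.0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    return (beta / beam.length_l) ** 2 * math.sqrt(beam.stiffness_ratio)


@dataclass(frozen=True)
class ModeSolution:
    """One free-vibration mode of a cantilevered barbule.

    ``beta`` is the dimensionless eigenvalue ``k l``; ``wavenumber_k`` its
    dimensional form ``beta / l`` [1/m]; ``sigma`` the mode-shape
    coefficient; ``omega_p`` the angular frequency [rad/s].
    """

    mode_index: int
    beta: float
    wavenumber_k: float
    sigma: float
    omega_p: float


def solve_modes(beam: BeamSection, n_modes: int, xtol: float = 1e-14) -> list[ModeSolution]:
    """Solve the cantilever eigenproblem for ``beam``: first ``n_modes`` modes."""
    betas = solve_eigenvalues(n_modes, xtol=xtol)
    return [
        ModeSolution(
            mode_index=j,
            beta=b,
            wavenumber_k=b / beam.length_l,
            sigma=sigma_coefficient(b),
            omega_p=natural_frequency(b, beam),
        )
        for j, b in enumerate(betas, start=1)
    ]


@dataclass(frozen=True)
class ExcitationAmplitude:
    """Modal amplitude of the first mode after a tip force is released.

    A steady tip force ``F`` deflects the cantilever statically by
    ``F l^3 / (3 E I_z)``; since the first mode's free-end shape value is
    2.000, the corresponding modal amplitude is ``C = F l^3 / (6 E I_z)``.
    ``phase_phi`` fixes where in the cycle ``t = 0`` falls.
    """

    tip_force_F: float
    amplitude_C: float
    phase_phi: float


def amplitude_from_tip_force(
    F: float, beam: BeamSection, phase_phi: float = math.pi / 2.0
) -> ExcitationAmplitude:
    """Amplitude constant ``C = F l^3 / (6 E I_z)`` for a released tip force.

    The default phase ``pi/2`` makes the ``t = 0`` displacement equal the
    static deflection shape with zero initial velocity — release from rest,
    as after a preening stroke lets go of the barbule.
    """
    if not math.isfinite(F):
        raise ValueError(f"tip force must be finite, got {F!r}")
    c = F * beam.length_l**3 / (6.0 * beam.young_E * beam.inertia_Iz)
    return ExcitationAmplitude(tip_force_F=F, amplitude_C=c, phase_phi=phase_phi)
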