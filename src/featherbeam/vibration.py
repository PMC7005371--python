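"""First-mode space-time response of a vibrating barbule.

After a preening or combing force at the tip is released, the barbule
oscillates in its first cantilever mode:

    y(x, t) = C Y1(x/l) sin(p1 t + phi),
    v(x, t) = p1 C Y1(x/l) cos(p1 t + phi),

where ``Y1`` is the first normalised mode shape and ``C`` the modal
amplitude set by the released tip force. Because the motion looks like a
rotation about the clamped root, the angular velocity is approximated by
``omega(t) = v(l, t) / l`` — a small-angle approximation taken literally,
with no arctangent correction.

The peak tip speed ``v_max = beta1^2 Y1(1) * C / l^2 * sqrt(E Iz / (rho A))``
(dimensionless coefficient 7.03203) is the speed imparted to a water drop
attached at the free end — the droplet-shedding speed. The drop is treated
as massless: its inertia does not alter the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beams import BeamSection
from .modal import ExcitationAmplitude, ModeSolution, mode_shape

__all__ = [
    "VibrationField",
    "TipKinematics",
    "displacement",
    "velocity",
    "angular_velocity",
    "tip_kinematics",
    "tip_timeseries",
]

#: Default time resolution used when scanning a period for extrema.
DEFAULT_SAMPLES_PER_PERIOD = 4096


@dataclass(frozen=True)
class VibrationField:
    """First-mode vibration state: beam, first mode, and excitation.

    The response formulas are first-mode only; constructing a field with a
    higher mode raises ``ValueError``.
    """

    beam: BeamSection
    mode: ModeSolution
    excitation: ExcitationAmplitude

    def __post_init__(self) -> None:
        if self.mode.mode_index != 1:
            raise ValueError(
                f"vibration response is defined for the first mode only, got mode {self.mode.mode_index}"
            )

    @property
    def period(self) -> float:
        """One vibration period ``2 pi / p1`` [s]."""
        return 2.0 * math.pi / self.mode.omega_p


def displacement(field: VibrationField, xi, time):
    """Transverse displacement ``y = C Y1(xi) sin(p1 t + phi)`` [m].

    ``xi`` is the dimensionless position ``x/l`` in ``[0, 1]``; ``time`` in
    seconds. Either may be an array (broadcast together).
    """
    shape = mode_shape(field.mode.beta, xi)
    phase = field.mode.omega_p * np.asarray(time, dtype=float) + field.excitation.phase_phi
    out = field.excitation.amplitude_C * shape * np.sin(phase)
    return out if np.ndim(out) else float(out)


def velocity(field: VibrationField, xi, time):
    """Transverse velocity ``v = p1 C Y1(xi) cos(p1 t + phi)`` [m/s].

    Exactly the time partial derivative of :func:`displacement`.
    """
    shape = mode_shape(field.mode.beta, xi)
    phase = field.mode.omega_p * np.asarray(time, dtype=float) + field.excitation.phase_phi
    out = field.mode.omega_p * field.excitation.amplitude_C * shape * np.cos(phase)
    return out if np.ndim(out) else float(out)


def angular_velocity(field: VibrationField, time):
    """Approximate root rotation rate ``omega(t) = v(l, t) / l`` [rad/s]."""
    v_tip = velocity(field, 1.0, time)
    return v_tip / field.beam.length_l


@dataclass(frozen=True)
class TipKinematics:
    """Peak tip speed and peak angular speed of the first mode.

    ``v_max = omega_max * l`` holds identically: the two share the
    coefficient ``beta1^2 Y1(1)`` and differ by one power of the length.
    ``v_max`` is the droplet-shedding speed.
    """

    v_max: float
    omega_max: float
    coefficient: float


def tip_kinematics(field: VibrationField) -> TipKinematics:
    """Peak tip speed and angular speed of the first-mode response.

    ``coeff = beta1^2 Y1(1)`` (= 7.03203 for the cantilever first mode),
    then ``v_max = coeff C / l^2 sqrt(E Iz/(rho A))`` and
    ``omega_max = v_max / l``.
    """
    beta = field.mode.beta
    coeff = beta**2 * mode_shape(beta, 1.0)
    c = abs(field.excitation.amplitude_C)
    scale = math.sqrt(field.beam.stiffness_ratio)
    # omega_max first, then v_max = omega_max * l, so the identity
    # omega_max * l == v_max holds exactly in floating point
    omega_max = coeff * c / field.beam.length_l**3 * scale
    v_max = omega_max * field.beam.length_l
    return TipKinematics(v_max=v_max, omega_max=omega_max, coefficient=coeff)


def tip_timeseries(
    field: VibrationField,
    n_periods: float = 1.0,
    samples_per_period: int = DEFAULT_SAMPLES_PER_PERIOD,
) -> pd.DataFrame:
    """Sample the tip response over ``n_periods`` of the first mode.

    Returns a DataFrame with columns ``time``, ``tip_displacement``,
    ``tip_velocity`` and ``angular_velocity``.
    """
    if samples_per_period < 2:
        raise ValueError("samples_per_period must be at least 2")
    n = max(int(round(n_periods * samples_per_period)), 2)
    t = np.linspace(0.0, n_periods * field.period, n)
    return pd.DataFrame(
        {
            "time": t,
            "tip_displacement": displacement(field, 1.0, t),
            "tip_velocity": velocity(field, 1.0, t),
            "angular_velocity": angular_velocity(field, t),
        }
    )
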