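"""Droplet-shedding speed of a vibrating barbule.

A preening force F applied at the barbule tip deflects it statically by
F l^3/(3 E Iz); releasing it excites the first cantilever mode with modal
amplitude C = F l^3/(6 E Iz). The peak tip speed, beta1^2 * Y1(1) = 7.03203
times C/l^2 * sqrt(E Iz/(rho A)), is the launch speed of a water drop
sitting at the free end.
"""

from featherbeam import (
    amplitude_from_tip_force,
    rectangular_section,
    solve_modes,
    tip_kinematics,
)
from featherbeam.vibration import VibrationField

beam = rectangular_section(
    length_l=300e-6, thickness_t=5e-6, width_w=10e-6, young_E=2.5e9, density_rho=1150.0
)
mode1 = solve_modes(beam, 1)[0]
excitation = amplitude_from_tip_force(F=1e-6, beam=beam)  # 1 uN tip force
field = VibrationField(beam=beam, mode=mode1, excitation=excitation)
kin = tip_kinematics(field)

print(f"modal amplitude C        : {excitation.amplitude_C * 1e6:.3f} um")
print(f"first natural frequency  : {mode1.omega_p / (2 * 3.141592653589793):.0f} Hz")
print(f"tip coefficient          : {kin.coefficient:.5f} (dimensionless)")
print(f"peak tip speed v_max     : {kin.v_max:.3f} m/s")
print(f"peak angular speed       : {kin.omega_max:.0f} rad/s")
print()
print("v_max is the speed handed to a droplet at the tip when the bent")
print("barbule snaps back - the mechanism that flings water off the feather.")
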