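"""Natural vibration modes of a single barbule.

Solves the clamped-free characteristic equation cos(beta) = -sech(beta) for
the first six dimensionless roots and converts them to natural frequencies
for a keratin barbule 300 um long, 5 um thick and 10 um wide. The roots are
universal (geometry-free); the frequencies scale with sqrt(E Iz / rho A)/l^2.
"""

from featherbeam import rectangular_section, solve_modes

beam = rectangular_section(
    length_l=300e-6, thickness_t=5e-6, width_w=10e-6, young_E=2.5e9, density_rho=1150.0
)

print(f"{'mode':>4} {'beta = k*l':>12} {'sigma':>8} {'omega [rad/s]':>14} {'f [kHz]':>9}")
for m in solve_modes(beam, 6):
    print(
        f"{m.mode_index:>4} {m.beta:>12.6f} {m.sigma:>8.4f} "
        f"{m.omega_p:>14.4g} {m.omega_p / (2 * 3.141592653589793) / 1e3:>9.2f}"
    )
print()
print("beta is the dimensionless eigenvalue; the first root 1.875104 sets the")
print("fundamental mode a preening stroke excites. sigma shapes the deflection")
print("profile; omega is the angular natural frequency of this barbule.")
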