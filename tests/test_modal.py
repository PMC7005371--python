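"""Cantilever eigenproblem: roots, sigma, mode shapes, frequencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featherbeam import (
    amplitude_from_tip_force,
    characteristic_residual,
    mode_shape,
    natural_frequency,
    rectangular_section,
    sigma_coefficient,
    solve_eigenvalues,
)

from conftest import TABLE_ROOTS, boundary_condition_residuals


def brute_force_roots(n: int, grid_step: float = 1e-3) -> list[float]:
    """Independent oracle: scan a fine grid for sign changes, then bisect."""

    def f(b):
        return math.cos(b) + 2.0 * math.exp(-b) / (1.0 + math.exp(-2.0 * b))

    roots = []
    b = grid_step
    prev = f(0.0)
    while len(roots) < n:
        cur = f(b)
        if prev * cur <= 0.0:
            lo, hi = b - grid_step, b
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0.0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
        prev = cur
        b += grid_step
    return roots


class TestCharacteristicResidual:
    @pytest.mark.parametrize("beta", TABLE_ROOTS[:2])
    def test_small_at_tabulated_roots(self, beta):
        assert abs(characteristic_residual(beta)) < 1e-5

    def test_value_at_zero(self):
        # cos 0 + sech 0 = 2
        assert characteristic_residual(0.0) == 2.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            characteristic_residual(-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_overflow_safe_everywhere(self, beta):
        r = characteristic_residual(beta)
        assert math.isfinite(r)
        assert -1.0 <= r <= 2.0  # cos in [-1,1], sech in (0,1]


class TestEigenvalues:
    def test_first_six_match_published_roots(self):
        betas = solve_eigenvalues(6)
        for got, printed in zip(betas, TABLE_ROOTS):
            assert abs(got - printed) < 1e-6

    def test_single_mode(self):
        (beta1,) = solve_eigenvalues(1)
        assert abs(beta1 - 1.875104) < 1e-6

    def test_seventh_root_near_asymptote_and_oracle(self):
        betas = solve_eigenvalues(7)
        assert abs(betas[6] - 13.0 * math.pi / 2.0) < 1e-4
        oracle = brute_force_roots(7)
        assert np.allclose(betas, oracle, rtol=0, atol=1e-9)

    def test_strictly_increasing(self):
        betas = solve_eigenvalues(12)
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))

    def test_residuals_below_refinement_tolerance(self):
        for b in solve_eigenvalues(10):
            assert abs(characteristic_residual(b)) < 1e-12

    def test_determinant_form_vanishes(self):
        # cos b cosh b + 1 = cosh b * residual(b); the scaled form is the
        # representable statement of the zero determinant. The raw form is
        # asserted where a double can express it (cosh b6 ~ 1.6e7 amplifies a
        # half-ulp of b into ~1.4e-8, so mode 6 cannot reach 1e-8).
        betas = solve_eigenvalues(6)
        for b in betas:
            assert abs(math.cos(b) * math.cosh(b) + 1.0) / math.cosh(b) < 1e-12
        for b in betas[:5]:
            assert abs(math.cos(b) * math.cosh(b) + 1.0) < 1e-8

    def test_asymptotic_alternation(self):
        # b_n approaches (2n-1)pi/2 from alternating sides, gap < 2 e^-b.
        # Limited to 10 modes: beyond that the gap (~e^-b) sinks below the
        # spacing of doubles near b itself (~eps*b) and is pure rounding.
        betas = solve_eigenvalues(10)
        gaps = [b - (2 * n - 1) * math.pi / 2.0 for n, b in enumerate(betas, start=1)]
        eps = np.finfo(float).eps
        for n, (b, gap) in enumerate(zip(betas, gaps), start=1):
            if n >= 2:
                # true gap is 2 e^-b (1 - e^-2b + ...), just under the bound;
                # allow the quantization noise of b itself (a few ulps)
                assert abs(gap) < 2.0 * math.exp(-b) + 8 * eps * b
        signs = [math.copysign(1.0, g) for g in gaps]
        assert all(s1 == -s2 for s1, s2 in zip(signs, signs[1:]))
        mags = [abs(g) for g in gaps]
        assert all(m1 > m2 for m1, m2 in zip(mags, mags[1:]))

    def test_tolerance_invariance_at_six_decimals(self):
        loose = solve_eigenvalues(6, xtol=1e-10)
        tight = solve_eigenvalues(6, xtol=1e-14)
        assert [round(b, 6) for b in loose] == [round(b, 6) for b in tight]

    def test_deterministic_across_calls(self):
        assert solve_eigenvalues(8) == solve_eigenvalues(8)

    def test_many_modes_do_not_overflow(self):
        betas = solve_eigenvalues(50)
        assert len(betas) == 50
        assert all(map(math.isfinite, betas))

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_mode_count_rejected(self, bad):
        with pytest.raises(ValueError):
            solve_eigenvalues(bad)


class TestSigma:
    def test_first_mode_value(self):
        beta1 = solve_eigenvalues(1)[0]
        assert round(sigma_coefficient(beta1), 4) == 0.7341

    def test_small_beta_limit(self):
        # series: (sinh - sin)/(cosh + cos) ~ (b^3/3)/2 -> 0
        assert sigma_coefficient(1e-4) == pytest.approx(1e-12 / 6.0, rel=1e-3)
        assert sigma_coefficient(0.0) == 0.0

    def test_matches_extended_precision_evaluation(self):
        # independent oracle: naive formula in 80-bit long double
        beta = solve_eigenvalues(2)[1]
        bl = np.longdouble(beta)
        naive = (np.sinh(bl) - np.sin(bl)) / (np.cosh(bl) + np.cos(bl))
        assert abs(sigma_coefficient(beta) - float(naive)) < 1e-10

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=600.0, max_value=1e5, allow_nan=False))
    def test_large_beta_tends_to_one(self, beta):
        s = sigma_coefficient(beta)
        assert math.isfinite(s)
        assert abs(s - 1.0) < 4.0 * math.exp(-min(beta, 700.0))


class TestModeShape:
    def test_clamped_root_is_zero(self):
        beta1 = solve_eigenvalues(1)[0]
        assert mode_shape(beta1, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_free_end_value_first_mode(self):
        beta1 = solve_eigenvalues(1)[0]
        assert round(mode_shape(beta1, 1.0), 3) == 2.000

    def test_clamped_slope_by_finite_difference(self):
        beta1 = solve_eigenvalues(1)[0]
        h = 1e-4
        slope = (-3 * mode_shape(beta1, 0.0) + 4 * mode_shape(beta1, h) - mode_shape(beta1, 2 * h)) / (2 * h)
        assert abs(slope) < 1e-6

    @pytest.mark.parametrize("mode_idx", [0, 1, 2])
    def test_all_four_boundary_conditions(self, mode_idx):
        # clamped-free: Y(0)=0, Y'(0)=0, Y''(1)=0, Y'''(1)=0 by one-sided
        # finite differences, relative to the mode's maximum amplitude
        beta = solve_eigenvalues(mode_idx + 1)[mode_idx]
        residuals = boundary_condition_residuals(beta, lambda x: mode_shape(beta, x))
        for r in residuals:
            assert r < 1e-5

    def test_domain_errors(self):
        beta1 = solve_eigenvalues(1)[0]
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                mode_shape(beta1, bad)

    def test_bit_stable_and_vectorized(self):
        beta = solve_eigenvalues(3)[2]
        xi = np.linspace(0, 1, 257)
        a, b = mode_shape(beta, xi), mode_shape(beta, xi)
        assert np.array_equal(a, b)
        assert a[100] == mode_shape(beta, float(xi[100]))

    def test_high_mode_stability(self):
        # exponential-difference form keeps cosh - sigma*sinh accurate; the
        # free-end value of every clamped-free mode is 2 in magnitude
        for beta in solve_eigenvalues(30)[25:]:
            assert abs(abs(mode_shape(beta, 1.0)) - 2.0) < 1e-6


class TestFrequencyAndAmplitude:
    def test_unit_beam_frequency_is_beta_squared(self, unit_beam):
        beta1 = solve_eigenvalues(1)[0]
        assert natural_frequency(beta1, unit_beam) == pytest.approx(3.516015, abs=1e-5)

    def test_length_scaling(self, barbule_section):
        beta1 = solve_eigenvalues(1)[0]
        doubled = rectangular_section(
            length_l=2 * barbule_section.length_l,
            thickness_t=5e-6,
            width_w=10e-6,
            young_E=barbule_section.young_E,
            density_rho=barbule_section.density_rho,
        )
        ratio = natural_frequency(beta1, barbule_section) / natural_frequency(beta1, doubled)
        assert ratio == pytest.approx(4.0, rel=1e-12)

    def test_modulus_scaling(self, barbule_section):
        beta1 = solve_eigenvalues(1)[0]
        stiffer = rectangular_section(
            length_l=barbule_section.length_l,
            thickness_t=5e-6,
            width_w=10e-6,
            young_E=4 * barbule_section.young_E,
            density_rho=barbule_section.density_rho,
        )
        ratio = natural_frequency(beta1, stiffer) / natural_frequency(beta1, barbule_section)
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_invalid_beta_rejected(self, barbule_section):
        with pytest.raises(ValueError):
            natural_frequency(-1.0, barbule_section)

    def test_zero_force_zero_amplitude(self, barbule_section):
        assert amplitude_from_tip_force(0.0, barbule_section).amplitude_C == 0.0

    def test_unit_cancellation(self, unit_beam):
        beam = rectangular_section(1.0, math.pow(12.0, 1 / 3), 1.0, 1.0, 1.0)
        assert beam.inertia_Iz == pytest.approx(1.0, rel=1e-12)
        amp = amplitude_from_tip_force(6.0, beam)
        assert amp.amplitude_C == pytest.approx(1.0, rel=1e-12)

    def test_amplitude_times_tip_shape_is_static_deflection(self, barbule_section):
        # C * Y(l)/C = F l^3 / (3 E Iz)
        beta1 = solve_eigenvalues(1)[0]
        F = 2.5e-6
        amp = amplitude_from_tip_force(F, barbule_section)
        static = F * barbule_section.length_l**3 / (3 * barbule_section.young_E * barbule_section.inertia_Iz)
        assert amp.amplitude_C * mode_shape(beta1, 1.0) == pytest.approx(static, rel=1e-12)
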