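"""Closed-form kernel algebra against quadrature oracles and symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import pulsefield as pf
from pulsefield.kernels import (
    DivergentIntegralError,
    exp_weighted_window,
    half_line_transform,
    half_line_transform_antiderivative,
    window_transform,
)

K = pf.presets.KERNEL


def quad_tail(f, a, scale, **kw):
    """Adaptive quadrature of an exponentially decaying integrand on [a, inf)."""
    kw.setdefault("limit", 800)
    return quad(f, a, a + 300.0 * scale, **kw)[0]


class TestWeightKernel:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(a_e=1.0, a_i=2.0, sigma_e=0.4, sigma_i=0.1),
            dict(a_e=5.0, a_i=-1.0, sigma_e=0.4, sigma_i=0.1),
            dict(a_e=5.0, a_i=1.0, sigma_e=0.1, sigma_i=0.4),
            dict(a_e=5.0, a_i=1.0, sigma_e=0.4, sigma_i=0.0),
        ],
    )
    def test_parameter_validation(self, bad):
        with pytest.raises(ValueError):
            pf.WeightKernel(**bad)

    def test_peak_value(self):
        # at the offset both exponentials are 1
        assert pf.weight(K.x0, K) == pytest.approx(K.a_e - K.a_i)
        assert pf.weight(3.0, K) == pytest.approx(4.0)

    @given(z=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_mirror_symmetry_about_offset(self, z):
        assert pf.weight(K.x0 + z, K) == pytest.approx(pf.weight(K.x0 - z, K), abs=1e-12)

    def test_decay_at_infinity(self):
        assert abs(pf.weight(1e3, K)) < 1e-30
        assert abs(pf.weight(-1e3, K)) < 1e-30


class TestWindowIntegral:
    def test_zero_length_window(self):
        assert pf.window_integral(1.7, 2.0, 2.0, K) == 0.0

    def test_against_quadrature(self, rng):
        for _ in range(30):
            xi = rng.uniform(-40, 40)
            d = rng.uniform(0.5, 30.0)
            ref = quad(lambda x: pf.weight(x, K), xi - d, xi, limit=400,
                       epsabs=1e-13, epsrel=1e-13,
                       points=[K.x0] if xi - d < K.x0 < xi else None)[0]
            assert pf.window_integral(xi, 0.0, d, K) == pytest.approx(ref, abs=1e-10)

    def test_two_sided_window_against_quadrature(self, rng):
        for _ in range(10):
            xi = rng.uniform(-20, 20)
            d1 = rng.uniform(-10, 5)
            d2 = d1 + rng.uniform(0.5, 25)
            ref = quad(lambda x: pf.weight(x, K), xi - d2, xi - d1, limit=400,
                       epsabs=1e-13, epsrel=1e-13,
                       points=[K.x0] if xi - d2 < K.x0 < xi - d1 else None)[0]
            assert pf.window_integral(xi, d1, d2, K) == pytest.approx(ref, abs=1e-10)

    def test_full_line_gives_total_mass(self):
        # window wide enough to capture everything
        val = pf.window_integral(0.0, -2e3, 2e3, K)
        assert val == pytest.approx(pf.total_mass(K), abs=1e-10)
        assert pf.total_mass(K) == pytest.approx(2 * (5 / 0.42 - 1 / 0.1))

    def test_vanishes_far_from_window(self):
        assert abs(pf.window_integral(1e3, 0.0, 5.0, K)) < 1e-30
        assert abs(pf.window_integral(-1e3, 0.0, 5.0, K)) < 1e-30


class TestHalfLineTransform:
    def test_against_quadrature_real(self, rng):
        for _ in range(20):
            z = rng.uniform(-30, 30)
            g = rng.uniform(0.03, 2.5)
            ref = quad_tail(lambda y: np.exp(-g * (y - z)) * pf.weight(y, K), z, 1 / g)
            assert half_line_transform(z, g, K) == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("g", [K.sigma_e, K.sigma_i])
    def test_degenerate_decay_equals_kernel_rate(self, g):
        for z in (-7.0, -1.0, 0.5):
            ref = quad_tail(lambda y: np.exp(-g * (y - z)) * pf.weight(y, K), z, 1 / g)
            assert half_line_transform(z, g, K) == pytest.approx(ref, abs=1e-8)

    def test_mirrored_side(self, rng):
        for _ in range(10):
            z = rng.uniform(-20, 20)
            g = rng.uniform(0.05, 1.5)
            ref = quad(
                lambda y: np.exp(-g * (z - y)) * pf.weight(y, K),
                z - 300 / g,
                z,
                limit=800,
            )[0]
            assert half_line_transform(z, g, K, side=-1) == pytest.approx(ref, abs=1e-8)

    def test_antiderivative_derivative_is_transform(self, rng):
        h = 1e-6
        for _ in range(10):
            z = rng.uniform(-15, 15)
            g = rng.uniform(0.05, 1.5)
            fd = (
                half_line_transform_antiderivative(z + h, g, K)
                - half_line_transform_antiderivative(z - h, g, K)
            ) / (2 * h)
            assert fd == pytest.approx(half_line_transform(z, g, K), abs=1e-6)

    def test_divergence_guard(self):
        with pytest.raises(DivergentIntegralError):
            half_line_transform(0.0, -0.2, K)


class TestConvolveWP:
    def test_decay_at_plus_infinity(self):
        assert abs(pf.convolve_wP(500.0, 0.3, 4.0, K)) < 1e-12

    def test_against_complex_quadrature(self, rng):
        c = 3.9
        for _ in range(12):
            xi = rng.uniform(-15, 15)
            lam = complex(rng.uniform(-0.9, 1.0), rng.uniform(-2, 2))
            g = (lam + 1) / c
            hi = xi + 60.0 / g.real
            pts = [K.x0] if xi < K.x0 < hi else None
            re = quad(
                lambda y: (np.exp(-g * (y - xi)) * pf.weight(y, K)).real,
                xi, hi, limit=2000, points=pts, epsabs=1e-12, epsrel=1e-12,
            )[0]
            im = quad(
                lambda y: (np.exp(-g * (y - xi)) * pf.weight(y, K)).imag,
                xi, hi, limit=2000, points=pts, epsabs=1e-12, epsrel=1e-12,
            )[0]
            assert pf.convolve_wP(xi, lam, c, K) == pytest.approx(re + 1j * im, abs=1e-8)

    def test_conjugation_symmetry(self, rng):
        for _ in range(10):
            lam = complex(rng.uniform(-0.9, 1), rng.uniform(-3, 3))
            xi = rng.uniform(-10, 10)
            a = pf.convolve_wP(xi, lam, 3.9, K)
            b = pf.convolve_wP(xi, np.conj(lam), 3.9, K)
            assert a == pytest.approx(np.conj(b), abs=1e-12)

    def test_domain_guard_left_of_essential_spectrum(self):
        with pytest.raises(DivergentIntegralError):
            pf.convolve_wP(0.0, -1.0, 4.0, K)
        with pytest.raises(DivergentIntegralError):
            pf.convolve_wP(0.0, -1.5 + 2j, 4.0, K)


class TestExpWeightedWindow:
    """The M_n / N_n building blocks of the piecewise profile."""

    def test_degenerate_interval_is_zero(self):
        # M2 evaluated at its own upper limit
        xi = K.x0 + 12.0
        assert exp_weighted_window(xi, 0.3, 2, (0.0, 12.0), K, direction=1) == pytest.approx(
            0.0, abs=1e-14
        )

    @pytest.mark.parametrize("branch", [1, 2, 3])
    def test_rightward_blocks_match_quadrature(self, branch, rng):
        d1, d2 = 0.0, 15.7
        uppers = {1: np.inf, 2: K.x0 + d2, 3: K.x0 + d1}
        for _ in range(8):
            g = rng.uniform(0.05, 1.2)
            if branch == 1:
                xi = K.x0 + d2 + rng.uniform(0, 8)
            elif branch == 2:
                xi = K.x0 + rng.uniform(d1, d2)
            else:
                xi = K.x0 + d1 - rng.uniform(0, 8)
            hi = uppers[branch] if np.isfinite(uppers[branch]) else xi + 300 / g
            ref = quad(
                lambda s: pf.window_integral(s, d1, d2, K) * np.exp(-g * s),
                xi,
                hi,
                limit=800,
            )[0]
            got = exp_weighted_window(xi, g, branch, (d1, d2), K, direction=1)
            assert got == pytest.approx(ref, abs=1e-8 * max(1, abs(ref)))

    @pytest.mark.parametrize("branch", [1, 2, 3])
    def test_leftward_blocks_match_quadrature(self, branch, rng):
        # leftward-moving waves use negative decay 1/v, v < 0
        d1, d2 = -3.3, 19.9
        lowers = {1: K.x0 + d2, 2: K.x0 + d1, 3: -np.inf}
        for _ in range(6):
            g = -1.0 / rng.uniform(1.5, 8.0)
            if branch == 1:
                xi = K.x0 + d2 + rng.uniform(0.5, 8)
            elif branch == 2:
                xi = K.x0 + rng.uniform(d1, d2)
            else:
                xi = K.x0 + d1 - rng.uniform(0.5, 8)
            lo = lowers[branch] if np.isfinite(lowers[branch]) else xi + 300 / g
            ref = quad(
                lambda s: pf.window_integral(s, d1, d2, K) * np.exp(-g * s),
                lo,
                xi,
                limit=800,
            )[0]
            got = exp_weighted_window(xi, g, branch, (d1, d2), K, direction=-1)
            assert got == pytest.approx(ref, abs=1e-8 * max(1, abs(ref)))

    def test_branch_assembly_equals_unified_profile(self):
        """Summing the M_n blocks per the piecewise listing reproduces the
        unified window-transform profile on every branch."""
        c, d = 3.9, 15.7
        g = 1.0 / c
        M = lambda xi, n: exp_weighted_window(xi, g, n, (0.0, d), K, direction=1)  # noqa: E731
        for xi in (-6.0, 1.0, K.x0 + 2.0, K.x0 + d - 1.0, K.x0 + d + 4.0):
            if xi <= K.x0:
                piecewise = M(xi, 3) + M(K.x0 + d, 1) + M(K.x0, 2)
            elif xi <= K.x0 + d:
                piecewise = M(xi, 2) + M(K.x0 + d, 1)
            else:
                piecewise = M(xi, 1)
            piecewise *= np.exp(g * xi) / c
            unified = window_transform(xi, 0.0, d, g, K) / c
            assert piecewise == pytest.approx(unified, abs=1e-10)

    def test_improper_divergence_guard(self):
        with pytest.raises(DivergentIntegralError):
            # positive decay toward -inf diverges
            exp_weighted_window(0.0, 0.5, 3, (0.0, 5.0), K, direction=-1)
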