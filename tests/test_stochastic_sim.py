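"""Langevin integrator: determinism, discretization identities, noise law,
and the noise-modified deterministic pulse."""

import numpy as np
import pytest

import pulsefield as pf
from pulsefield.stochastic_sim import _kernel_samples

K = pf.presets.KERNEL
KAPPA = 4.0
FIRING = pf.FiringRule(kappa=KAPPA)


def measured_speed(rec, level=KAPPA, edge="leading"):
    idx = 1 if edge == "leading" else 0
    pos = []
    prev = None
    for m in range(rec.times.size):
        tr_le = pf.level_crossings(rec.x, rec.fields[0, m], level, prev=prev)
        prev = tr_le
        pos.append(tr_le[idx])
    return np.polyfit(rec.times, pos, 1)[0]


class TestValidation:
    def test_noise_model_guards(self):
        with pytest.raises(ValueError):
            pf.NoiseModel(eps=-0.1)
        with pytest.raises(ValueError):
            pf.NoiseModel(eps=0.1, C0=0.0)
        with pytest.raises(NotImplementedError):
            pf.NoiseModel(eps=0.1, corr_len=1.0)

    def test_grid_guards(self):
        with pytest.raises(ValueError):
            pf.SimGrid(x_min=0.0, x_max=0.5, dx=0.1, dt=0.01, T=1.0)
        with pytest.raises(ValueError):
            pf.SimGrid(x_min=0.0, x_max=50.0, dx=0.1, dt=0.01, T=1.0, boundary="torus")

    def test_lattice_noise_requires_C0_matching_dx(self, stable_pulse):
        grid = pf.SimGrid(x_min=-20, x_max=40, dx=0.2, dt=0.01, T=0.1)
        noise = pf.NoiseModel(eps=0.005, C0=10.0)  # 1/dx = 5 != 10
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        with pytest.raises(ValueError, match="C0 = 1/dx"):
            pf.integrate_langevin(grid, K, FIRING, noise, u0=u0)

    def test_blowup_guard(self, stable_pulse):
        grid = pf.SimGrid(x_min=-20, x_max=40, dx=0.1, dt=0.01, T=1.0)
        noise = pf.NoiseModel(eps=0.0, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        u0[10] = np.nan
        with pytest.raises(FloatingPointError):
            pf.integrate_langevin(grid, K, FIRING, noise, u0=u0)

    def test_boundary_proximity_warns(self, stable_pulse):
        # domain so short the pulse runs into the right buffer
        grid = pf.SimGrid(x_min=-10, x_max=30, dx=0.1, dt=0.01, T=4.0)
        noise = pf.NoiseModel(eps=0.0, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        with pytest.warns(UserWarning, match="boundary"):
            pf.integrate_langevin(grid, K, FIRING, noise, u0=u0)


class TestDeterministicTransport:
    def test_pulse_travels_at_predicted_speed_without_reshaping(self, stable_pulse):
        grid = pf.SimGrid(x_min=-30, x_max=90, dx=0.1, dt=0.01, T=10.0)
        noise = pf.NoiseModel(eps=0.0, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        rec = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, record_every=1.0)
        speed = measured_speed(rec)
        # first-order lattice bias ~4% at dx=0.1, dt=0.01
        assert speed == pytest.approx(stable_pulse.c, rel=0.05)
        # shape preserved: final width near analytic width
        tr, le = pf.level_crossings(rec.x, rec.fields[0, -1], KAPPA)
        assert le - tr == pytest.approx(stable_pulse.d, rel=0.03)

    def test_speed_converges_first_order_in_dt(self, stable_pulse):
        speeds = {}
        for dt in (0.02, 0.01, 0.005):
            grid = pf.SimGrid(x_min=-30, x_max=70, dx=0.1, dt=dt, T=8.0)
            noise = pf.NoiseModel(eps=0.0, C0=10.0)
            u0 = pf.pulse_initial_condition(stable_pulse, grid)
            rec = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, record_every=1.0)
            speeds[dt] = measured_speed(rec)
        d1 = speeds[0.02] - speeds[0.01]
        d2 = speeds[0.01] - speeds[0.005]
        assert abs(d2) < abs(d1)  # successive refinement shrinks the change
        assert abs(d1) / max(abs(d2), 1e-12) == pytest.approx(2.0, rel=0.75)

    def test_locking_from_zero_initial_condition(self):
        """A strong slow stimulus entrains the field from rest to the
        analytic locked profile."""
        s = pf.StimulusSpec(I0=8.0, width_d=5.0, v=3.0)
        locked = pf.solve_locked(K, s, KAPPA)[0]
        grid = pf.SimGrid(x_min=-80, x_max=220, dx=0.1, dt=0.01, T=50.0)
        noise = pf.NoiseModel(eps=0.0, C0=10.0)
        rec = pf.integrate_langevin(
            grid, K, FIRING, noise, u0=np.zeros(grid.x.size), stimulus=s,
            record_every=5.0,
        )
        # lattice locking carries an O(dx)-scale spatial offset, so compare
        # crossing positions and width rather than a sup norm over steep edges
        t_end = rec.times[-1]
        tr, le = pf.level_crossings(rec.x, rec.fields[0, -1], KAPPA)
        assert tr - s.v * t_end == pytest.approx(locked.d1, abs=0.6)
        assert le - s.v * t_end == pytest.approx(locked.d2, abs=0.6)
        assert le - tr == pytest.approx(locked.width, abs=0.6)
        # and the plateau/tail values away from the edges do agree pointwise
        ref = locked.profile(rec.x - s.v * t_end)
        flat = np.abs(np.gradient(ref, grid.dx)) < 0.5
        core = (rec.x - s.v * t_end > locked.d1 - 15) & (rec.x - s.v * t_end < locked.d2 + 15)
        sel = flat & core
        assert np.max(np.abs(rec.fields[0, -1][sel] - ref[sel])) < 0.3


class TestNoiseLaw:
    def test_identical_seed_bit_identical(self, stable_pulse):
        grid = pf.SimGrid(x_min=-20, x_max=50, dx=0.1, dt=0.01, T=1.0)
        noise = pf.NoiseModel(eps=0.005, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        a = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, n_trials=3, seed=7)
        b = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, n_trials=3, seed=7)
        assert np.array_equal(a.fields, b.fields)
        c = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, n_trials=3, seed=8)
        assert not np.array_equal(a.fields, c.fields)

    def test_increment_variance_matches_lattice_law(self, stable_pulse):
        """One Euler step: Var(dU_noise) = 2 C0 dt eps g(U)^2 per site."""
        grid = pf.SimGrid(x_min=-20, x_max=50, dx=0.1, dt=0.01, T=0.01)
        noise = pf.NoiseModel(eps=0.005, g0=1.0, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        n_trials = 4000
        rec = pf.integrate_langevin(
            grid, K, FIRING, noise, u0=u0, n_trials=n_trials, record_every=0.01, seed=3
        )
        du = rec.fields[:, 1, :].astype(float) - u0[None, :]
        # subtract the deterministic drift (identical across trials)
        du = du - du.mean(axis=0, keepdims=True)
        var = du.var(axis=0, ddof=1)
        expected = 2.0 * noise.C0 * grid.dt * noise.eps * (noise.g0 * u0) ** 2
        sel = np.abs(u0) > 0.5  # sites where the signal dominates float32 rounding
        ratio = var[sel] / expected[sel]
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)

    def test_novikov_midpoint_identity(self, stable_pulse, rng):
        """Stratonovich mean drift: eps^{1/2} <g(U_mid) dW> = eps C0 g'(U) g(U) dt.

        Checked at a frozen field with the same increment convention the
        integrator uses (per-site variance 2 C0 dt)."""
        noise = pf.NoiseModel(eps=0.005, g0=1.0, C0=10.0)
        dt = 0.01
        u = np.linspace(0.5, 5.0, 10)
        n = 200_000
        dW = np.sqrt(2.0 * noise.C0 * dt) * rng.standard_normal((n, u.size))
        u_next = u[None, :] + np.sqrt(noise.eps) * noise.g(u)[None, :] * dW
        g_mid = noise.g(0.5 * (u[None, :] + u_next))
        # control variate: <g(U_n) dW> = 0 exactly (Ito), so subtracting it
        # removes the dominant Monte-Carlo variance without changing the mean
        lhs = np.sqrt(noise.eps) * np.mean((g_mid - noise.g(u)[None, :]) * dW, axis=0)
        rhs = noise.novikov_drift(u) * dt
        assert np.allclose(lhs, rhs, rtol=0.05, atol=1e-8)


class TestEffectivePulse:
    def test_zero_noise_reduces_to_free_pulse(self, stable_pulse):
        ep = pf.effective_pulse(K, KAPPA, pf.NoiseModel(eps=0.0, C0=10.0))
        assert ep.c_eps == pytest.approx(stable_pulse.c, abs=1e-8)
        assert ep.width == pytest.approx(stable_pulse.d, abs=1e-8)

    def test_gamma_identity(self, effective, noise):
        assert effective.Gamma * effective.c_eps + noise.strat_shift == pytest.approx(1.0)

    def test_threshold_conditions(self, effective):
        assert effective.profile(0.0) == pytest.approx(KAPPA, abs=1e-8)
        assert effective.profile(effective.width) == pytest.approx(KAPPA, abs=1e-8)

    def test_linear_gain_required(self):
        with pytest.raises(ValueError):
            pf.effective_pulse(K, KAPPA, pf.NoiseModel(eps=0.01, g_kind="additive"))

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            pf.effective_pulse(K, KAPPA, pf.NoiseModel(eps=0.2, g0=1.0, C0=10.0))


class TestPulseInitialCondition:
    def test_sampled_crossings_near_analytic(self, stable_pulse):
        grid = pf.SimGrid(x_min=-30, x_max=60, dx=0.1, dt=0.01, T=1.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        tr, le = pf.level_crossings(grid.x, u0, KAPPA)
        assert abs(tr - 0.0) < grid.dx
        assert abs(le - stable_pulse.d) < grid.dx

    def test_offset_shifts_crossings(self, stable_pulse):
        grid = pf.SimGrid(x_min=-30, x_max=60, dx=0.1, dt=0.01, T=1.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid, offset=7.3)
        tr, le = pf.level_crossings(grid.x, u0, KAPPA)
        assert abs(tr - 7.3) < grid.dx

    def test_zero_noise_keeps_two_crossings(self, stable_pulse):
        grid = pf.SimGrid(x_min=-30, x_max=80, dx=0.1, dt=0.01, T=6.0)
        noise = pf.NoiseModel(eps=0.0, C0=10.0)
        u0 = pf.pulse_initial_condition(stable_pulse, grid)
        rec = pf.integrate_langevin(grid, K, FIRING, noise, u0=u0, record_every=1.0)
        for m in range(rec.times.size):
            above = rec.fields[0, m] > KAPPA
            flips = np.count_nonzero(above[:-1] != above[1:])
            assert flips == 2
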