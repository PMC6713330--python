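"""Spatial integrator: Laplacian, no-flux conservation, Rush-Larsen, episodes."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis.strategies import floats as st_floats

from spiralchaos.grid import Grid
from spiralchaos.integrator import (
    NumericsConfig,
    StabilityError,
    TissueState,
    laplacian9,
    run_episode,
    step,
)
from spiralchaos.models import BOCFState, bocf_gating_rhs


class TestLaplacian:
    def test_constant_field_is_zero_everywhere(self):
        f = np.full((10, 13), 3.7)
        np.testing.assert_array_equal(laplacian9(f, 0.5), 0.0)

    def test_linear_field_zero_in_interior(self):
        y, x = np.mgrid[0:20, 0:25].astype(float)
        lap = laplacian9(2.0 * x - 3.0 * y, 1.0)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_quadratic_field_exact(self):
        # nine-point stencil is exact for quadratics: lap(x^2) = 2
        y, x = np.mgrid[0:15, 0:15].astype(float)
        lap = laplacian9(x ** 2, 1.0)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 2.0, rtol=1e-12)

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError):
            laplacian9(np.zeros((2, 5)), 1.0)

    def test_nonfinite_rejected_in_debug(self):
        f = np.zeros((5, 5)); f[2, 2] = np.inf
        with pytest.raises(ValueError):
            laplacian9(f, 1.0, check_finite=True)


class TestStep:
    def test_uniform_rest_is_fixed_point(self, bocf_params, bocf_cfg):
        g = Grid(12, 12, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        ref = st.copy()
        for _ in range(200):
            step(st, bocf_params, bocf_cfg)
        np.testing.assert_allclose(st.cell.u, ref.cell.u, atol=1e-12)
        np.testing.assert_allclose(st.cell.v, ref.cell.v, atol=1e-12)
        np.testing.assert_allclose(st.cell.s, ref.cell.s, atol=1e-10)

    def test_diffusion_conserves_mass(self, bocf_params, bocf_cfg, rng,
                                      small_grid):
        # no-flux boundaries: with reaction off, the discrete integral of u
        # is invariant over 1000 steps to relative 1e-10
        st = TissueState.resting("bocf", small_grid, bocf_params)
        st.cell.u = rng.random(small_grid.shape)
        m0 = st.cell.u.sum()
        for _ in range(1000):
            step(st, bocf_params, bocf_cfg, diffusion_only=True)
        assert abs(st.cell.u.sum() - m0) / m0 < 1e-10

    def test_rush_larsen_is_exact_for_frozen_rates(self, bocf_params,
                                                   bocf_cfg):
        # at constant u the gate update is the closed-form exponential, so
        # n steps must land exactly on the analytic solution at t = n dt
        p, dt = bocf_params, bocf_cfg.dt
        st = BOCFState.resting(shape=(3, 3), p=p)
        st.u = np.full((3, 3), 0.5)
        g = Grid(3, 3, 1.0)
        ts = TissueState("bocf", g, st)
        _, (v_inf, tau_v, *_ ) = bocf_gating_rhs(st, p)
        v0 = st.v.copy()
        n = 500
        # diffusion of u would drift rates: hold u frozen by resetting
        for _ in range(n):
            u_save = ts.cell.u.copy()
            step(ts, p, bocf_cfg)
            ts.cell.u = u_save
        exact = v_inf - (v_inf - v0) * np.exp(-n * dt / tau_v)
        np.testing.assert_allclose(ts.cell.v, exact, rtol=1e-12)

    @given(y=st_floats(0.0, 1.0), y_inf=st_floats(0.0, 1.0),
           tau=st_floats(1e-6, 1e3), dt=st_floats(1e-9, 10.0))
    @settings(deadline=None, max_examples=200)
    def test_rush_larsen_update_unconditionally_bounded(self, y, y_inf,
                                                        tau, dt):
        # the exponential update interpolates between y and y_inf for ANY
        # dt > 0, so gates can never leave [0, 1] regardless of step size
        new = y_inf - (y_inf - y) * np.exp(-dt / tau)
        assert 0.0 <= new <= 1.0
        assert min(y, y_inf) - 1e-15 <= new <= max(y, y_inf) + 1e-15

    def test_stability_guard_refuses_large_dt(self, bocf_params):
        cfg = NumericsConfig(dt=5e-3, h=1.0)
        g = Grid(8, 8, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        with pytest.raises(StabilityError):
            step(st, bocf_params, cfg)


class TestPlaneWave:
    @staticmethod
    def _front_speed(params, cfg, n_x=180, n_steps=2500):
        g = Grid(n_x, 5, cfg.h)
        st = TissueState.resting("bocf", g, params)
        stim = np.zeros(g.shape)
        stim[:, :max(3, int(round(3.0 / cfg.h)))] = -150.0   # 3 mm strip
        stim_steps = int(round(0.01 / cfg.dt))               # 10 ms pulse
        pos, ts = [], []
        for i in range(n_steps):
            step(st, params, cfg,
                 stimulus=stim if i < stim_steps else None,
                 check_stability=False)
            if i % 200 == 0:
                ex = st.cell.u > 0.5
                if ex.any():
                    pos.append(np.max(np.nonzero(ex.any(axis=0))[0]) * cfg.h)
                    ts.append(st.t)
        return np.polyfit(ts[2:], pos[2:], 1)[0]

    def test_speed_positive_and_increases_with_D(self, bocf_params, bocf_cfg):
        v1 = self._front_speed(bocf_params, bocf_cfg)
        v2 = self._front_speed(replace(bocf_params, D=300.0), bocf_cfg)
        assert v1 > 100.0            # mm/s, physiological order
        assert v2 > v1

    def test_grid_refinement_consistency(self, bocf_params):
        # successive refinements of (h, dt) change the conduction speed by
        # shrinking amounts: the scheme is consistent and converging
        v1 = self._front_speed(bocf_params, NumericsConfig(dt=1e-4, h=1.0))
        v2 = self._front_speed(bocf_params, NumericsConfig(dt=5e-5, h=0.5),
                               n_x=360, n_steps=5000)
        v3 = self._front_speed(bocf_params, NumericsConfig(dt=2.5e-5, h=0.25),
                               n_x=720, n_steps=10000)
        assert abs(v3 - v2) < abs(v2 - v1)
        assert abs(v3 - v2) / v3 < 0.15


class TestRunEpisode:
    def test_resting_state_terminates_immediately(self, bocf_params,
                                                  bocf_cfg):
        g = Grid(10, 10, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        rec = run_episode(st, bocf_params, bocf_cfg, t_max=1.0)
        assert rec.status == "terminated"
        assert rec.lifetime < 0.02

    def test_persistent_activity_is_censored(self, bocf_params, bocf_cfg):
        # a fresh plane wave outlives a tiny t_max -> censored at t_max
        g = Grid(60, 20, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        st.cell.u[:, :6] = 1.0
        rec = run_episode(st, bocf_params, bocf_cfg, t_max=0.05)
        assert rec.status == "censored"
        assert rec.lifetime == pytest.approx(0.05)

    def test_deterministic_replay(self, bocf_params, bocf_cfg, rng):
        g = Grid(20, 20, 1.0)
        results = []
        for _ in range(2):
            st = TissueState.resting("bocf", g, bocf_params)
            st.cell.u = np.zeros(g.shape)
            st.cell.u[5:9, 5:9] = 1.2
            for _ in range(400):
                step(st, bocf_params, bocf_cfg)
            results.append(st.cell.u.copy())
        np.testing.assert_array_equal(results[0], results[1])
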