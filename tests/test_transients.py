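"""Termination detection, survival curves, escape-rate and scaling fits."""

import numpy as np
import pytest

from spiralchaos.grid import Grid
from spiralchaos.integrator import TissueState
from spiralchaos.records import CENSORED, TERMINATED
from spiralchaos.synthetic import synthetic_lifetimes, synthetic_scaling_samples
from spiralchaos.transients import (
    EscapeRateEstimator,
    SupertransientScalingFit,
    detect_termination,
    fit_escape_rate,
    fit_supertransient_scaling,
    survival_curve,
)


class TestDetectTermination:
    def test_resting_state_after_window(self, bocf_params):
        g = Grid(10, 10, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        assert detect_termination(st, bocf_params, quiet_time=0.25)
        assert not detect_termination(st, bocf_params, quiet_time=0.0)

    def test_active_state_is_not_terminated(self, bocf_params):
        g = Grid(10, 10, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        st.cell.u[4, 4] = 1.0
        assert not detect_termination(st, bocf_params, quiet_time=10.0)

    def test_lifetime_is_last_crossing_not_window_end(self, bocf_params,
                                                      bocf_cfg):
        # a decaying sub-threshold tail must not inflate the lifetime by
        # the confirmation window
        from spiralchaos.integrator import run_episode
        g = Grid(12, 12, 1.0)
        st = TissueState.resting("bocf", g, bocf_params)
        st.cell.u[:] = bocf_params.theta_v * 0.9   # sub-threshold, decaying
        rec = run_episode(st, bocf_params, bocf_cfg, t_max=1.0,
                          confirm_window=0.2)
        assert rec.status == TERMINATED
        assert rec.lifetime < 0.05                 # not ~0.2


class TestSurvivalCurve:
    def test_direct_counts(self):
        lts = [(1.0, TERMINATED), (2.0, TERMINATED), (4.0, TERMINATED)]
        c = survival_curve(lts, t_grid=np.array([0.0, 3.0, 5.0]))
        assert c.n_ch[0] == 3          # t = 0 -> all
        assert c.n_ch[1] == 1          # t = 3 -> only the 4 s episode
        assert c.n_ch[2] == 0          # beyond max lifetime

    def test_censored_episodes_count_until_censor_time(self):
        lts = [(1.0, TERMINATED), (2.0, CENSORED)]
        c = survival_curve(lts, t_grid=np.array([0.0, 1.5, 2.0]))
        assert list(c.n_ch) == [2, 1, 1]

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            survival_curve([])

    def test_nonincreasing_with_full_start(self, rng):
        lts = [(float(T), TERMINATED) for T in rng.exponential(2.0, 50)]
        c = survival_curve(lts)
        assert c.n_ch[0] == 50
        assert np.all(np.diff(c.n_ch) <= 0)


class TestEscapeRate:
    def test_exact_recovery_on_noise_free_curve(self):
        # points lying exactly on 200 exp(-0.5 t) must give kappa = 0.5
        from spiralchaos.transients import SurvivalCurve
        t = np.linspace(0, 10, 60)
        curve = SurvivalCurve(t=t, n_ch=200 * np.exp(-0.5 * t), n=200)
        fit = EscapeRateEstimator(n_bootstrap=0).fit(curve)
        assert fit.kappa_ == pytest.approx(0.5, rel=1e-6)
        assert fit.avg_lifetime_ == pytest.approx(2.0, rel=1e-6)

    def test_threshold_count_matches_fraction(self):
        lt = synthetic_lifetimes(0.2, 200, seed=0)
        fit = fit_escape_rate(lt, fit_threshold_fraction=0.10)
        assert fit.fit_threshold_ == pytest.approx(20.0)

    def test_monte_carlo_recovery(self):
        # 100 replicate ensembles of 200 Exponential(0.2) lifetimes:
        # mean estimate within 3 SE of truth, relative RMSE < 15%
        kappa = 0.2
        est = np.array([
            EscapeRateEstimator(n_bootstrap=0).fit(
                synthetic_lifetimes(kappa, 200, seed=500 + r)).kappa_
            for r in range(100)])
        se = est.std(ddof=1) / 10.0
        assert abs(est.mean() - kappa) < 3 * se
        assert np.sqrt(((est - kappa) ** 2).mean()) / kappa < 0.15

    def test_predict_reproduces_curve(self):
        lt = synthetic_lifetimes(0.3, 200, seed=4)
        fit = fit_escape_rate(lt)
        pred = fit.predict([0.0])
        assert 150 <= pred[0] <= 250

    def test_sklearn_params_roundtrip(self):
        est = EscapeRateEstimator(fit_threshold_fraction=0.2, n_bootstrap=7)
        assert est.get_params()["fit_threshold_fraction"] == 0.2
        est.set_params(n_bootstrap=3)
        assert est.n_bootstrap == 3


class TestScalingFit:
    def test_noise_free_identifiability(self):
        areas = np.array([0.5, 1, 2, 4, 8]) * 1e5
        samp = synthetic_scaling_samples(1e-5, 1.2, areas, 0.0, 0)
        A, T = zip(*samp)
        fit = fit_supertransient_scaling(A, T)
        assert fit.a_tilde_ == pytest.approx(1e-5, rel=1e-6)
        assert fit.gamma_ == pytest.approx(1.2, rel=1e-6)

    def test_gamma_one_is_exactly_linear(self):
        areas = np.array([1, 2, 3, 5]) * 1e5
        T = np.exp(2e-5 * areas)
        fit = fit_supertransient_scaling(areas, T)
        assert fit.gamma_ == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(np.log(fit.predict(areas)), np.log(T),
                                   rtol=1e-9)

    def test_area_rescaling_equivariance(self):
        # areas scaled by c: a_tilde scales by 1/c, gamma unchanged
        areas = np.array([1, 2, 4, 8]) * 1e5
        T = np.exp((1.3e-5 * areas) ** 1.15)
        f1 = fit_supertransient_scaling(areas, T)
        f2 = fit_supertransient_scaling(10.0 * areas, T)
        assert f2.gamma_ == pytest.approx(f1.gamma_, rel=1e-9)
        assert f2.a_tilde_ == pytest.approx(f1.a_tilde_ / 10.0, rel=1e-9)

    def test_short_lifetimes_rejected_with_message(self):
        with pytest.raises(ValueError, match="exceed 1 s"):
            fit_supertransient_scaling([1e5, 2e5, 4e5], [0.5, 2.0, 3.0])

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_supertransient_scaling([1e5, 2e5], [5.0, 9.0])
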