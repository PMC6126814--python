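"""Circular run-and-tumble model: closed forms, estimators, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import hookmotility as hm
from hookmotility.rtmodel import CorrelationCurve
from hookmotility.tracks import Trajectory


class TestClosedForms:
    def test_acf_circular_values(self):
        assert hm.acf_circular(0.0, 3.0) == 1.0
        assert hm.acf_circular(1.0, np.pi) == pytest.approx(-1.0)
        assert hm.acf_circular(2.0, 0.5) == pytest.approx(np.cos(1.0))

    def test_msd_circular_values(self):
        assert hm.msd_circular(0.0, 2.0, 1.0) == 0.0
        # antipode: ψt = π gives the squared diameter 4s²
        assert hm.msd_circular(np.pi, 2.0, 1.0) == pytest.approx(16.0)

    def test_msd_short_time_is_ballistic(self):
        v = 1.0 * 2.0
        assert hm.msd_circular(0.01, 2.0, 1.0) == pytest.approx(v**2 * 0.01**2,
                                                                rel=1e-4)

    def test_msd_bounded_and_periodic(self):
        t = np.linspace(0, 50, 1000)
        vals = hm.msd_circular(t, 3.0, 0.7)
        assert np.all(vals <= 4 * 9.0 + 1e-9)
        assert np.allclose(vals, hm.msd_circular(t + 2 * np.pi / 0.7, 3.0, 0.7))

    @settings(max_examples=30, deadline=None)
    @given(lam=st.sampled_from([0.1, 1.0, 10.0]),
           t=st.one_of(st.just(0.0), st.floats(1e-3, 100.0)))
    def test_population_acf_matches_quadrature(self, lam, t):
        closed = hm.acf_population_exponential(t, lam)
        if t > 0:
            num, _ = quad(lambda p: lam * np.exp(-lam * p), 0, np.inf,
                          weight="cos", wvar=t, limit=500, limlst=500)
        else:
            num = 1.0
        assert abs(closed - num) < 1e-8

    def test_population_acf_limits(self):
        assert hm.acf_population_exponential(0.0, 2.0) == 1.0
        lam = 3.0
        assert hm.acf_population_exponential(lam, lam) == pytest.approx(0.5)
        t = np.linspace(0, 1000, 10000)
        vals = hm.acf_population_exponential(t, lam)
        assert np.all(vals > 0)            # never crosses zero
        assert vals[-1] == pytest.approx(lam**2 / t[-1]**2, rel=1e-3)

    def test_rt_acf_limits(self):
        t = np.linspace(0, 10, 50)
        assert np.allclose(hm.acf_circular_rt(t, 1.2, 0.0), hm.acf_circular(t, 1.2))
        assert np.allclose(hm.acf_circular_rt(t, 0.0, 0.5), np.exp(-0.5 * t))

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            hm.acf_population_exponential(1.0, 0.0)
        with pytest.raises(ValueError):
            hm.acf_circular_rt(1.0, 1.0, -0.1)


class TestEmpiricalCurves:
    def test_straight_track_acf_is_one(self):
        t = np.arange(100) * 0.1
        traj = Trajectory(t, 20 * t, 5 * t)
        acf = hm.empirical_acf(traj, 5.0)
        assert np.allclose(acf.values, 1.0, atol=1e-12)

    def test_exact_circle_acf_is_cosine(self):
        t = np.arange(400) * 0.05
        s = 20.0
        traj = Trajectory(t, s * np.cos(t), s * np.sin(t))
        acf = hm.empirical_acf(traj, 10.0)
        assert np.allclose(acf.values, np.cos(acf.lags), atol=1e-9)

    def test_reversing_track_acf_minus_one(self):
        t = np.arange(50) * 0.1
        x = np.zeros(50)
        x[1::2] = 1.0
        acf = hm.empirical_acf(Trajectory(t, x, np.zeros(50)), 0.1)
        assert acf.values[1] == pytest.approx(-1.0)

    def test_static_track_msd_zero(self):
        t = np.arange(50) * 0.1
        msd = hm.empirical_msd(Trajectory(t, np.ones(50), np.ones(50)), 2.0)
        assert np.allclose(msd.values, 0.0)

    def test_ballistic_track_msd_quadratic(self):
        t = np.arange(100) * 0.1
        msd = hm.empirical_msd(Trajectory(t, 12.0 * t, np.zeros(100)), 3.0)
        assert np.allclose(msd.values, 12.0**2 * msd.lags**2, rtol=1e-9, atol=1e-9)

    def test_overlong_lag_truncated_with_warning(self, caplog):
        t = np.arange(50) * 0.1
        traj = Trajectory(t, t, t)
        acf = hm.empirical_acf(traj, 100.0)
        assert acf.lags[-1] <= 4.9

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            CorrelationCurve(lags=[1.0, 0.5], values=[0, 0])


class TestFitting:
    def test_noiseless_cosine_self_consistency(self):
        t = np.arange(0, 10, 0.1)
        acf = CorrelationCurve(lags=t, values=np.cos(0.8 * t))
        msd = CorrelationCurve(lags=t, values=2 * (20 / 0.8)**2 *
                               (1 - np.cos(0.8 * t)), kind="msd")
        fit = hm.fit_circular_rt(acf, msd)
        assert fit.params.psi == pytest.approx(0.8, abs=1e-6)
        assert fit.params.tumble_rate == pytest.approx(0.0, abs=1e-5)

    def test_parameter_recovery_from_simulation(self):
        cfg = hm.SimulationConfig(n_cells=1000, duration=50.0, dt=0.1,
                                  psi_value=1.2, tumble_rate=0.4, speed_mean=20.0,
                                  speed_rel_width=0.0, rot_diffusion=0.0,
                                  box_size=1e6, seed=21)
        ts = hm.simulate_circular_rt(cfg).unwrapped()
        acf = hm.empirical_acf(ts, 10.0)
        msd = hm.empirical_msd(ts, 10.0)
        fit = hm.fit_circular_rt(acf, msd)
        assert fit.params.psi == pytest.approx(1.2, rel=0.10)
        assert fit.params.tumble_rate == pytest.approx(0.4, rel=0.20)
        assert fit.params.v == pytest.approx(20.0, rel=0.05)
        assert fit.params.s == pytest.approx(20.0 / 1.2, rel=0.12)

    def test_fit_scale_equivariance(self):
        cfg = hm.SimulationConfig(n_cells=100, duration=30.0, dt=0.1,
                                  psi_value=1.0, tumble_rate=0.3, speed_mean=20.0,
                                  speed_rel_width=0.0, rot_diffusion=0.0,
                                  box_size=1e6, seed=22)
        ts = hm.simulate_circular_rt(cfg).unwrapped()
        acf = hm.empirical_acf(ts, 8.0)
        msd = hm.empirical_msd(ts, 8.0)
        fit1 = hm.fit_circular_rt(acf, msd)
        scaled = CorrelationCurve(lags=msd.lags, values=9.0 * msd.values,
                                  n_pairs=msd.n_pairs, kind="msd")
        fit3 = hm.fit_circular_rt(acf, scaled)
        assert fit3.params.v == pytest.approx(3 * fit1.params.v, rel=1e-9)
        assert fit3.params.s == pytest.approx(3 * fit1.params.s, rel=1e-9)
        assert fit3.params.psi == pytest.approx(fit1.params.psi, rel=1e-9)

    def test_population_mode_recovers_lambda(self):
        t = np.arange(0, 10, 0.1)
        lam = 2.5
        acf = CorrelationCurve(lags=t, values=hm.acf_population_exponential(t, lam))
        msd = CorrelationCurve(lags=t, values=(15.0 * t)**2, kind="msd")
        fit = hm.fit_circular_rt(acf, msd, population=True)
        assert fit.params.psi_lambda == pytest.approx(lam, rel=1e-4)

    def test_too_few_lags_rejected(self):
        t = np.arange(0, 0.5, 0.1)
        acf = CorrelationCurve(lags=t, values=np.cos(t))
        msd = CorrelationCurve(lags=t, values=t**2, kind="msd")
        with pytest.raises(ValueError):
            hm.fit_circular_rt(acf, msd)
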