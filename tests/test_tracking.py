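"""Tracking statistics: features, HMM tumble detection, CVE, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans

import hookmotility as hm
from hookmotility.tracks import TrackSet, Trajectory


def _straight(v=20.0, n=50, dt=0.1, angle=0.0):
    t = np.arange(n) * dt
    return Trajectory(t, v * t * np.cos(angle), v * t * np.sin(angle))


def _circle(psi=1.0, v=20.0, n=200, dt=0.1):
    t = np.arange(n) * dt
    s = v / psi
    return Trajectory(t, s * np.cos(psi * t), s * np.sin(psi * t))


class TestFrameFeatures:
    def test_uniform_straight_motion(self):
        f = hm.compute_frame_features(_straight())
        assert np.allclose(f.speed, 20.0)
        assert np.allclose(f.angular_velocity, 0.0, atol=1e-9)
        assert np.allclose(f.relative_acceleration, 0.0, atol=1e-9)
        assert np.allclose(f.angular_acceleration, 0.0, atol=1e-9)

    def test_exact_circle_angular_velocity(self):
        dt = 0.05
        f = hm.compute_frame_features(_circle(psi=1.0, dt=dt))
        # chord headings advance by exactly ψ·dt per frame
        assert np.allclose(f.angular_velocity, 1.0, atol=1e-9)

    def test_sharp_turn_maximizes_angular_acceleration(self):
        dt = 0.1
        t = np.arange(40) * dt
        x = np.where(t < 2.0, 20 * t, 40.0)
        y = np.where(t < 2.0, 0.0, 20 * (t - 2.0))
        f = hm.compute_frame_features(Trajectory(t, x, y))
        turn = np.argmax(np.abs(f.angular_acceleration))
        # features are aligned to interior frames starting at index 1
        assert abs((turn + 1) * dt - 2.0) <= 2 * dt

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hm.compute_frame_features(Trajectory([0, 0.1, 0.2], [0, 1, 2], [0, 0, 0]))

    @settings(max_examples=20, deadline=None)
    @given(angle=st.floats(0, 2 * np.pi), shift=st.floats(-100, 100))
    def test_rigid_motion_invariance(self, angle, shift):
        base = hm.simulate_circular_rt(hm.SimulationConfig(
            n_cells=1, duration=10, dt=0.1, tumble_rate=0.3, rot_diffusion=0.06,
            seed=11, box_size=1e6)).unwrapped().trajectories[0]
        f0 = hm.compute_frame_features(base)
        c, s = np.cos(angle), np.sin(angle)
        rx = c * base.x - s * base.y + shift
        ry = s * base.x + c * base.y + shift
        f1 = hm.compute_frame_features(Trajectory(base.times, rx, ry))
        assert np.allclose(f0.speed, f1.speed, rtol=1e-6, atol=1e-6)
        assert np.allclose(np.abs(f0.angular_velocity), np.abs(f1.angular_velocity),
                           rtol=1e-6, atol=1e-5)


class TestTumbleHMM:
    def test_training_invariant_to_trajectory_order(self, reference_tracks,
                                                    tumble_model):
        reordered = TrackSet(list(reversed(reference_tracks.trajectories)),
                             config=reference_tracks.config,
                             ground_truth=reference_tracks.ground_truth)
        m2 = hm.train_tumble_model(reordered)
        assert np.allclose(tumble_model.means, m2.means, atol=1e-6)
        assert np.allclose(tumble_model.transition_matrix, m2.transition_matrix,
                           atol=1e-6)

    def test_emission_means_match_kmeans_on_separated_clusters(self):
        # two constructed populations: straight runs (features near zero) vs
        # constant-amplitude zigzags (|angular acceleration| = 4δ/dt²)
        rng = np.random.default_rng(30)
        dt, n, v, delta = 0.1, 200, 20.0, 0.3
        times = np.arange(n) * dt
        trajs = []
        for c in range(12):
            if c % 2 == 0:
                headings = np.zeros(n - 1)
            else:
                headings = delta * (-1.0) ** np.arange(n - 1)
            steps = v * dt * np.column_stack([np.cos(headings), np.sin(headings)])
            pos = np.concatenate([[np.zeros(2)], np.cumsum(steps, axis=0)])
            pos += rng.normal(0, 1e-4, size=pos.shape)
            trajs.append(Trajectory(times, pos[:, 0], pos[:, 1], cell_id=c))
        tracks = TrackSet(trajs)
        model = hm.train_tumble_model(tracks)
        X = np.concatenate([hm.compute_frame_features(t).matrix() for t in tracks])
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        centers = km.cluster_centers_[np.argsort(km.cluster_centers_[:, 1])]
        sep = centers[1, 1] - centers[0, 1]
        assert abs(model.means[1, 1] - centers[1, 1]) / sep < 0.10
        assert abs(model.means[0, 1] - centers[0, 1]) / sep < 0.10

    def test_smooth_swimmers_decode_almost_never_tumbling(self, tumble_model):
        cfg = hm.SimulationConfig(n_cells=60, duration=60.0, dt=0.1,
                                  speed_mean=25.0, speed_rel_width=0.2,
                                  psi_value=1.0, tumble_rate=0.0,
                                  rot_diffusion=0.06, box_size=1e6, seed=12)
        smooth = hm.simulate_circular_rt(cfg)
        biases = [hm.classify_tumbles(t, tumble_model)[1] for t in smooth]
        assert np.mean(biases) < 0.02

    def test_noiseless_straight_track_has_zero_bias(self, tumble_model):
        _, bias, events = hm.classify_tumbles(_straight(n=100), tumble_model)
        assert bias == 0.0 and events == []

    def test_recovered_bias_and_event_count(self, tumble_model):
        cfg = hm.SimulationConfig(n_cells=300, duration=60.0, dt=0.1,
                                  speed_mean=25.0, speed_rel_width=0.2,
                                  psi_value=1.0, tumble_rate=0.5,
                                  rot_diffusion=0.06, tumble_duration_mean=0.15,
                                  box_size=1e6, seed=13)
        ts = hm.simulate_circular_rt(cfg)
        biases, occs, n_events, n_true = [], [], 0, 0
        for traj in ts:
            states, tb, ev = hm.classify_tumbles(traj, tumble_model)
            ct = ts.ground_truth[traj.cell_id]
            biases.append(tb)
            occs.append(ct.tumbling[1:len(states) + 1].mean())
            n_events += len(ev)
            n_true += ct.n_tumbles
        assert abs(np.mean(biases) - np.mean(occs)) < 0.05
        assert abs(n_events / n_true - 1.0) < 0.15

    def test_bias_monotone_in_tumble_rate(self, tumble_model):
        medians = []
        for rate in (0.0, 0.5, 1.0):
            cfg = hm.SimulationConfig(n_cells=80, duration=60.0, dt=0.1,
                                      speed_mean=25.0, speed_rel_width=0.2,
                                      psi_value=1.0, tumble_rate=rate,
                                      rot_diffusion=0.06,
                                      tumble_duration_mean=0.15,
                                      box_size=1e6, seed=14)
            ts = hm.simulate_circular_rt(cfg)
            medians.append(np.median([hm.classify_tumbles(t, tumble_model)[1]
                                      for t in ts]))
        assert medians[0] <= medians[1] <= medians[2]


class TestDiffusionCVE:
    def test_static_track_zero(self):
        t = np.arange(0, 40, 0.1)
        D, flagged = hm.estimate_diffusion_cve(
            Trajectory(t, np.ones_like(t), np.ones_like(t)))
        assert D == 0.0 and not flagged

    def test_brownian_ensemble_unbiased(self):
        ts = hm.simulate_brownian(1000, 100.0, 0.1, D=1.0, seed=15)
        Ds = [hm.estimate_diffusion_cve(t)[0] for t in ts]
        assert np.mean(Ds) == pytest.approx(1.0, rel=0.05)

    def test_localization_noise_cancels(self):
        clean = hm.simulate_brownian(600, 100.0, 0.1, D=1.0, seed=16)
        noisy = hm.simulate_brownian(600, 100.0, 0.1, D=1.0, loc_noise=0.3, seed=16)
        D_clean = np.mean([hm.estimate_diffusion_cve(t)[0] for t in clean])
        D_noisy = np.mean([hm.estimate_diffusion_cve(t)[0] for t in noisy])
        se = np.std([hm.estimate_diffusion_cve(t)[0] for t in noisy],
                    ddof=1) / np.sqrt(600)
        assert abs(D_noisy - D_clean) < 3 * se

    def test_short_track_rejected(self):
        t = np.arange(0, 20, 0.1)
        with pytest.raises(ValueError):
            hm.estimate_diffusion_cve(Trajectory(t, t, t), resample_interval=10.0)


class TestPersistence:
    @pytest.mark.parametrize("D,v0,tau", [(50.0, 10.0, 1.0), (0.0, 5.0, 0.0),
                                          (-10.0, 10.0, -0.2)])
    def test_relation(self, D, v0, tau):
        assert hm.directional_persistence(D, v0) == pytest.approx(tau)

    def test_zero_speed_undefined(self):
        with pytest.raises(ValueError):
            hm.directional_persistence(1.0, 0.0)

    def test_run_and_tumble_tau_matches_inverse_rate(self):
        # ψ=0 run-and-tumble with uniform reorientation: τ = 1/tumble_rate
        cfg = hm.SimulationConfig(n_cells=600, duration=100.0, dt=0.1,
                                  psi_value=0.0, tumble_rate=0.5, speed_mean=20.0,
                                  speed_rel_width=0.0, rot_diffusion=0.0,
                                  box_size=1e6, seed=17)
        stats = hm.summarize_population(hm.simulate_circular_rt(cfg).unwrapped())
        assert stats["tau_s"].mean() == pytest.approx(2.0, rel=0.15)


class TestPopulationSummary:
    def test_single_cell_population_mean_is_cell_value(self):
        ts = TrackSet([_straight(v=18.0, n=200)])
        stats = hm.summarize_population(ts)
        assert len(stats) == 1
        assert stats.v0_um_s.iloc[0] == pytest.approx(18.0)

    def test_filters_slow_and_short_tracks(self):
        slow = _straight(v=1.0, n=200)
        fast = _straight(v=20.0, n=200)
        short = _straight(v=20.0, n=5)
        stats = hm.summarize_population(TrackSet([slow, fast, short]))
        assert len(stats) == 1

    def test_empty_input_gives_empty_summary(self):
        stats = hm.summarize_population(TrackSet([]))
        assert stats.empty

    def test_pooled_mean_speed_recovers_truth(self):
        cfg = hm.SimulationConfig(n_cells=600, duration=20.0, dt=0.1,
                                  speed_mean=25.0, speed_rel_width=0.2,
                                  psi_value=1.0, tumble_rate=0.0,
                                  rot_diffusion=0.0, box_size=1e6, seed=18)
        stats = hm.summarize_population(hm.simulate_circular_rt(cfg).unwrapped(),
                                        min_duration=5.0)
        se = stats.v0_um_s.std(ddof=1) / np.sqrt(len(stats))
        assert abs(stats.v0_um_s.mean() - 25.0) < 3 * se
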