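import pytest

import hookmotility as hm

SEED = 1


@pytest.fixture(scope="session")
def reference_tracks():
    """Wild-type-like quasi-2D tracks with finite-duration tumbles."""
    cfg = hm.SimulationConfig(n_cells=150, duration=60.0, dt=0.1, speed_mean=25.0,
                              speed_rel_width=0.2, psi_value=1.0, tumble_rate=0.5,
                              rot_diffusion=0.06, tumble_duration_mean=0.15,
                              box_size=1e6, seed=SEED)
    return hm.simulate_circular_rt(cfg)


@pytest.fixture(scope="session")
def tumble_model(reference_tracks):
    return hm.train_tumble_model(reference_tracks)


@pytest.fixture(scope="session")
def small_straight_movie():
    """128-px movie of straight bulk swimmers at 25 μm/s, S=0.2, 100 fps."""
    tracks = hm.simulate_swimmers_3d(150, 12.0, 0.01, speed_mean=25.0,
                                     speed_rel_width=0.2, box_size=64.0,
                                     tumble_rate=0.0, seed=SEED)
    optics = hm.OpticsConfig(image_size=128, pixel_size=0.5)
    return hm.render_movie(tracks, optics, seed=SEED + 1)
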