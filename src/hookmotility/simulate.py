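"""Seeded generators for every input the analysis pipeline consumes.

The central generator is :func:`simulate_circular_rt`, a quasi-2D circular
run-and-tumble process: near a surface, hydrodynamic interactions curve
bacterial runs into circular arcs, so each cell moves at constant tangential
speed v on a circle of radius s = v/ψ (ψ the angular velocity of the circular
motion), reorienting completely at exponentially distributed tumble times.
Population heterogeneity of curvature is modelled as ψ ~ Exponential(λ),
i.e. P(ψ) = λ e^{-λψ}.

:func:`simulate_swimmers_3d` generates bulk (3D) straight run-and-tumble
swimmers projected onto the image plane; this is the fixture for the
DDM virtual-microscope experiments, where the per-speed intermediate
scattering function of isotropic 3D swimmers is exactly sinc(qvτ).

:func:`simulate_brownian` provides non-motile controls for the
covariance-based diffusion estimator, and :func:`sample_hook_lengths`
generates molecular-ruler calibration data (hook length vs ruler length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tracks import CellTruth, TrackSet, Trajectory

__all__ = [
    "SimulationConfig",
    "HookMeasurementSet",
    "simulate_circular_rt",
    "simulate_swimmers_3d",
    "simulate_brownian",
    "sample_hook_lengths",
]

# Angular diffusivity applied to the heading while a finite-duration tumble is
# in progress (rad²/s).  Over a mean 0.15 s tumble this reorients the heading
# by ~1.2 rad RMS — comparable to measured bacterial tumble angles — and the
# frame-to-frame angular jerk it produces is what the HMM detector keys on.
TUMBLE_ROT_DIFFUSION = 5.0


@dataclass
class SimulationConfig:
    """Parameters of the quasi-2D circular run-and-tumble generator.

    Defaults mirror the standard tracking experiment: 10 fps for 100 s over
    a ~1.3 mm² field of view, swimming speeds around 25 μm/s with relative
    spread S = σ/v = 0.2, run lengths of ~2 s (tumble_rate 0.5 /s).
    """

    n_cells: int = 100
    duration: float = 100.0          # s
    dt: float = 0.1                  # s (10 fps)
    box_size: float = 1140.0         # μm, square periodic domain
    speed_mean: float = 25.0         # μm/s
    speed_rel_width: float = 0.2     # S = σ/v
    psi_mode: str = "fixed"          # "fixed" | "exponential"
    psi_value: float = 1.0           # rad/s, fixed mode
    psi_lambda: float = 1.0          # 1/(rad/s), exponential mode: P(ψ)=λe^{-λψ}
    tumble_rate: float = 0.5         # 1/s
    rot_diffusion: float = 0.0       # rad²/s
    seed: int = 0
    mixed_psi_signs: bool = False    # default: single handedness (surface swimming)
    tumble_duration_mean: float = 0.0   # s; 0 → instantaneous tumbles
    tumble_speed_frac: float = 0.3      # speed multiplier while tumbling
    loc_noise: float = 0.0           # μm, i.i.d. localization noise

    def __post_init__(self) -> None:
        vals = [self.duration, self.dt, self.box_size, self.speed_mean,
                self.speed_rel_width, self.psi_value, self.psi_lambda,
                self.tumble_rate, self.rot_diffusion, self.tumble_duration_mean,
                self.tumble_speed_frac, self.loc_noise]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite value in SimulationConfig")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.speed_mean < 0:
            raise ValueError("speed_mean must be >= 0")
        if not (0 <= self.speed_rel_width < 1):
            raise ValueError("speed_rel_width must be in [0, 1)")
        if self.tumble_rate < 0:
            raise ValueError("tumble_rate must be >= 0")
        if self.psi_mode not in ("fixed", "exponential"):
            raise ValueError("psi_mode must be 'fixed' or 'exponential'")
        if self.psi_mode == "exponential" and self.psi_lambda <= 0:
            raise ValueError("psi_lambda must be > 0 in exponential mode")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _draw_speeds(rng, n, mean, rel_width):
    """Per-cell speeds from a Schulz (gamma) law with ⟨v⟩=mean, σ/⟨v⟩=rel_width."""
    if mean == 0 or rel_width == 0:
        return np.full(n, float(mean))
    shape = 1.0 / rel_width**2
    return rng.gamma(shape, mean / shape, size=n)


def _draw_tumble_times(rng, rate, duration):
    """Exact event times of a Poisson process on (0, duration]."""
    if rate <= 0:
        return np.empty(0)
    # over-draw waiting times, extend in the (rare) case the sum falls short
    n_guess = max(8, int(rate * duration + 6 * math.sqrt(rate * duration) + 8))
    gaps = rng.exponential(1.0 / rate, size=n_guess)
    while gaps.sum() < duration:
        gaps = np.concatenate([gaps, rng.exponential(1.0 / rate, size=n_guess)])
    times = np.cumsum(gaps)
    return times[times <= duration]


def _arc_displacements(theta0, dtheta, arclen):
    """Chord displacement of constant-speed motion along a circular arc.

    theta0 : heading at arc start; dtheta : total heading change over the
    step; arclen : speed·dt.  Exact for constant angular velocity within the
    step, so a noiseless simulated circle lies exactly on radius v/ψ.
    """
    dtheta = np.asarray(dtheta, dtype=float)
    out_x = np.empty_like(dtheta)
    out_y = np.empty_like(dtheta)
    small = np.abs(dtheta) < 1e-12
    t1 = theta0 + dtheta
    with np.errstate(divide="ignore", invalid="ignore"):
        r = arclen / dtheta
        out_x = r * (np.sin(t1) - np.sin(theta0))
        out_y = r * (-np.cos(t1) + np.cos(theta0))
    if np.any(small):
        out_x = np.where(small, arclen * np.cos(theta0), out_x)
        out_y = np.where(small, arclen * np.sin(theta0), out_y)
    return out_x, out_y


def simulate_circular_rt(config: SimulationConfig) -> TrackSet:
    """Simulate a population of quasi-2D circular run-and-tumble swimmers.

    Each cell draws a tangential speed v (Schulz law of relative width S) and
    an angular velocity ψ (fixed or Exponential(λ)), then advances its heading
    by ψ·dt per frame plus Gaussian rotational noise of variance
    2·rot_diffusion·dt.  Tumbles occur at exponentially distributed waiting
    times; at a tumble the heading is redrawn uniformly on [0, 2π).  With
    ``tumble_duration_mean > 0`` tumbles instead last an exponential duration
    during which speed drops to ``tumble_speed_frac``·v and the heading
    diffuses strongly (partial reorientation, ~1.2 rad RMS per mean tumble).

    Positions are wrapped into the periodic box; unwrapped coordinates and
    per-cell (ψ, v, tumble times, tumble occupancy) are kept in
    ``ground_truth``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt

    speeds = _draw_speeds(rng, cfg.n_cells, cfg.speed_mean, cfg.speed_rel_width)
    if cfg.psi_mode == "fixed":
        psis = np.full(cfg.n_cells, float(cfg.psi_value))
    else:
        psis = rng.exponential(1.0 / cfg.psi_lambda, size=cfg.n_cells)
    if cfg.mixed_psi_signs:
        psis = psis * rng.choice([-1.0, 1.0], size=cfg.n_cells)

    x0 = rng.uniform(0, cfg.box_size, size=cfg.n_cells)
    y0 = rng.uniform(0, cfg.box_size, size=cfg.n_cells)
    theta0 = rng.uniform(0, 2 * np.pi, size=cfg.n_cells)

    trajectories = []
    truth = {}
    finite = cfg.tumble_duration_mean > 0
    rot_sd = math.sqrt(2 * cfg.rot_diffusion * cfg.dt)
    jit_sd = math.sqrt(2 * TUMBLE_ROT_DIFFUSION * cfg.dt)

    for c in range(cfg.n_cells):
        t_tumble = _draw_tumble_times(rng, cfg.tumble_rate, cfg.duration)
        tumbling = np.zeros(n_steps + 1, dtype=bool)
        if finite and t_tumble.size:
            durations = rng.exponential(cfg.tumble_duration_mean, size=t_tumble.size)
            # tumbles occupy [start, end); overlapping intervals simply merge
            ends = np.minimum(t_tumble + durations, cfg.duration)
            for s_, e_ in zip(t_tumble, ends):
                i0 = int(np.ceil(s_ / cfg.dt))
                i1 = int(np.ceil(e_ / cfg.dt))
                tumbling[i0:i1 + 1] = True
            # reorientation is carried by the strong in-tumble angular jitter;
            # no extra heading jump at tumble end, so the kinematic anomaly
            # stays confined to the tumble interval itself
            reset_frames = np.empty(0, int)
        else:
            # instantaneous: heading redrawn from the first frame after the event
            reset_frames = np.minimum(np.ceil(t_tumble / cfg.dt).astype(int) + 1,
                                      n_steps) if t_tumble.size else np.empty(0, int)

        noise = rng.normal(0.0, rot_sd, size=n_steps) if rot_sd > 0 else np.zeros(n_steps)
        if finite:
            in_tumble_step = tumbling[:-1]
            noise = noise + np.where(in_tumble_step,
                                     rng.normal(0.0, jit_sd, size=n_steps), 0.0)
        dtheta = psis[c] * cfg.dt + noise

        # heading with uniform redraw at reset frames (offset trick keeps it
        # vectorized: theta = cumulative rotation + piecewise-constant offset)
        base = np.concatenate([[theta0[c]], theta0[c] + np.cumsum(dtheta)])
        if len(reset_frames):
            reset_frames = np.asarray(reset_frames, int)
            new_headings = rng.uniform(0, 2 * np.pi, size=len(reset_frames))
            offsets = new_headings - base[reset_frames]
            idx = np.searchsorted(reset_frames, np.arange(n_steps + 1), side="right")
            offset_per_frame = np.concatenate([[0.0], offsets])[idx]
            theta = base + offset_per_frame
        else:
            theta = base

        speed_step = np.full(n_steps, speeds[c])
        if finite:
            speed_step = np.where(tumbling[:-1], cfg.tumble_speed_frac * speeds[c],
                                  speed_step)
        dx, dy = _arc_displacements(theta[:-1], dtheta, speed_step * cfg.dt)
        x_true = x0[c] + np.concatenate([[0.0], np.cumsum(dx)])
        y_true = y0[c] + np.concatenate([[0.0], np.cumsum(dy)])

        x_obs = np.mod(x_true, cfg.box_size)
        y_obs = np.mod(y_true, cfg.box_size)
        if cfg.loc_noise > 0:
            x_obs = x_obs + rng.normal(0, cfg.loc_noise, size=x_obs.size)
            y_obs = y_obs + rng.normal(0, cfg.loc_noise, size=y_obs.size)

        trajectories.append(Trajectory(times, x_obs, y_obs, cell_id=c))
        truth[c] = CellTruth(psi=psis[c], speed=speeds[c], tumble_times=t_tumble,
                             tumbling=tumbling if finite else None,
                             x_true=x_true, y_true=y_true)

    return TrackSet(trajectories, config=cfg, ground_truth=truth)


def simulate_swimmers_3d(n_cells: int, duration: float, dt: float,
                         speed_mean: float = 25.0, speed_rel_width: float = 0.2,
                         box_size: float = 128.0, tumble_rate: float = 0.0,
                         diffusion: float = 0.0, seed: int = 0) -> TrackSet:
    """Bulk straight/run-and-tumble swimmers projected onto the image plane.

    Directions are isotropic on the 3D sphere and redrawn uniformly at
    exponentially distributed tumbles; only the in-plane (x, y) coordinates
    are reported.  ``diffusion`` adds isotropic translational Brownian motion
    (μm²/s).  This is the canonical DDM fixture: the intermediate scattering
    function of isotropic 3D swimmers at fixed speed is sinc(q·v·τ).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    speeds = _draw_speeds(rng, n_cells, speed_mean, speed_rel_width)

    trajectories = []
    truth = {}
    for c in range(n_cells):
        t_tumble = _draw_tumble_times(rng, tumble_rate, duration)
        # one direction per run segment, applied per frame
        seg_start = np.concatenate([[0.0], t_tumble])
        n_seg = seg_start.size
        phi = rng.uniform(0, 2 * np.pi, size=n_seg)
        cos_th = rng.uniform(-1, 1, size=n_seg)
        sin_th = np.sqrt(1 - cos_th**2)
        dirs = np.column_stack([sin_th * np.cos(phi), sin_th * np.sin(phi), cos_th])
        seg_of_step = np.searchsorted(t_tumble, times[:-1] + dt / 2)
        step_dirs = dirs[seg_of_step]
        disp = speeds[c] * dt * step_dirs
        if diffusion > 0:
            disp = disp + rng.normal(0, math.sqrt(2 * diffusion * dt), size=disp.shape)
        pos = np.concatenate([[np.zeros(3)], np.cumsum(disp, axis=0)])
        pos[:, 0] += rng.uniform(0, box_size)
        pos[:, 1] += rng.uniform(0, box_size)
        x_true, y_true = pos[:, 0], pos[:, 1]
        trajectories.append(Trajectory(times, np.mod(x_true, box_size),
                                       np.mod(y_true, box_size), cell_id=c))
        truth[c] = CellTruth(psi=0.0, speed=speeds[c], tumble_times=t_tumble,
                             x_true=x_true, y_true=y_true)
    cfg = SimulationConfig(n_cells=n_cells, duration=duration, dt=dt,
                           box_size=box_size, speed_mean=speed_mean,
                           speed_rel_width=speed_rel_width, psi_mode="fixed",
                           psi_value=0.0, tumble_rate=tumble_rate, seed=seed)
    return TrackSet(trajectories, config=cfg, ground_truth=truth)


def simulate_brownian(n_cells: int, duration: float, dt: float, D: float,
                      loc_noise: float = 0.0, seed: int = 0,
                      box_size: float = 1140.0) -> TrackSet:
    """Pure Brownian controls: Gaussian increments of variance 2·D·dt per axis.

    Optional i.i.d. localization noise of SD ``loc_noise`` (μm) is added to
    the reported positions only; ground truth keeps the noiseless path.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    sd = math.sqrt(2 * D * dt)

    trajectories = []
    truth = {}
    for c in range(n_cells):
        steps = (rng.normal(0, sd, size=(n_steps, 2)) if sd > 0
                 else np.zeros((n_steps, 2)))
        pos = np.concatenate([[np.zeros(2)], np.cumsum(steps, axis=0)])
        pos[:, 0] += rng.uniform(0, box_size)
        pos[:, 1] += rng.uniform(0, box_size)
        x_obs, y_obs = pos[:, 0].copy(), pos[:, 1].copy()
        if loc_noise > 0:
            x_obs += rng.normal(0, loc_noise, size=x_obs.size)
            y_obs += rng.normal(0, loc_noise, size=y_obs.size)
        trajectories.append(Trajectory(times, x_obs, y_obs, cell_id=c))
        truth[c] = CellTruth(psi=0.0, speed=0.0, x_true=pos[:, 0], y_true=pos[:, 1])
    return TrackSet(trajectories, ground_truth=truth)


@dataclass
class HookMeasurementSet:
    """Hook-length measurements against molecular-ruler (FliK) length.

    ``data`` has one row per measured hook: columns ``flik_length`` (amino
    acids), ``hook_length`` (nm) and ``controlled`` (bool; mutants with
    uncontrolled hook length are excluded from ruler fits).
    """

    data: pd.DataFrame
    slope: Optional[float] = None      # nm per amino acid, generative truth
    intercept: Optional[float] = None  # nm
    noise_sd: Optional[float] = None   # nm

    def __post_init__(self) -> None:
        required = {"flik_length", "hook_length"}
        if not required.issubset(self.data.columns):
            raise ValueError("data must have flik_length and hook_length columns")
        if "controlled" not in self.data.columns:
            self.data = self.data.assign(controlled=True)
        if (self.data["flik_length"] <= 0).any():
            raise ValueError("flik_length must be > 0")
        if (self.data["hook_length"] <= 0).any():
            raise ValueError("hook_length must be > 0")


def sample_hook_lengths(slope: float, intercept: float,
                        flik_lengths: Sequence[float], n_per: int,
                        noise_sd: float, seed: int = 0) -> HookMeasurementSet:
    """Hook lengths Gaussian-scattered around the linear ruler law.

    hook_length ~ Normal(slope·flik + intercept, noise_sd²), resampled (not
    clipped) to stay positive.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    flik = np.asarray(flik_lengths, dtype=float)
    if np.any(flik <= 0):
        raise ValueError("flik lengths must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for f in flik:
        mu = slope * f + intercept
        if mu <= 0 and noise_sd == 0:
            raise ValueError(f"ruler law gives nonpositive hook length at flik={f}")
        vals = rng.normal(mu, noise_sd, size=n_per) if noise_sd > 0 else np.full(n_per, mu)
        for _ in range(100):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = rng.normal(mu, noise_sd, size=int(bad.sum()))
        rows.append(pd.DataFrame({"flik_length": f, "hook_length": vals}))
    data = pd.concat(rows, ignore_index=True)
    return HookMeasurementSet(data=data, slope=slope, intercept=intercept,
                              noise_sd=noise_sd)
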