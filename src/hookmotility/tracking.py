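"""Per-trajectory behavioral statistics for quasi-2D single-cell tracking.

The pipeline mirrors standard bacterial swim-tracking practice: frame-level
kinematic features (speed, heading, angular velocity, relative and angular
acceleration), a two-state hidden Markov model over (relative acceleration,
|angular acceleration|) separating "swimming" from "tumbling" frames, a
covariance-based estimator (CVE) of the effective diffusion coefficient on
timescales beyond rotational diffusion, and the directional persistence
τ defined through D = ½ v₀² τ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .tracks import TrackSet, Trajectory

__all__ = [
    "FrameFeatures",
    "TumbleModel",
    "compute_frame_features",
    "train_tumble_model",
    "classify_tumbles",
    "estimate_diffusion_cve",
    "directional_persistence",
    "summarize_population",
]

log = logging.getLogger(__name__)

_SPEED_EPS = 1e-9  # μm/s floor for the track-mean speed normalization


@dataclass
class FrameFeatures:
    """Kinematic features aligned on the trajectory's interior frames.

    All arrays share one length; for an n-point trajectory that length is
    n − 3 (speed needs one displacement, angular acceleration needs three).
    """

    speed: np.ndarray                  # μm/s
    heading: np.ndarray                # rad
    angular_velocity: np.ndarray       # rad/s, wrapped to (−π/dt, π/dt]
    relative_acceleration: np.ndarray  # 1/s, speed change / (dt · mean speed)
    angular_acceleration: np.ndarray   # rad/s²

    def matrix(self) -> np.ndarray:
        """(L, 2) HMM feature matrix: (relative_acceleration, |angular_acceleration|)."""
        return np.column_stack([self.relative_acceleration,
                                np.abs(self.angular_acceleration)])


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return -((-a + np.pi) % (2 * np.pi) - np.pi)


def compute_frame_features(traj: Trajectory) -> FrameFeatures:
    """Frame-level speed, heading, angular velocity and accelerations.

    Speeds and headings come from frame-to-frame displacements; the angular
    velocity is the wrapped heading change per dt; the relative acceleration
    is the fractional speed change per unit time, normalized by the
    track-mean speed so the feature is scale-free across slow and fast cells.
    """
    if traj.n_points < 4:
        raise ValueError("need at least 4 points to compute frame features")
    dt = traj.dt
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    speed = np.hypot(dx, dy) / dt                      # length n-1
    heading = np.arctan2(dy, dx)                       # length n-1
    angvel = _wrap_angle(np.diff(heading)) / dt        # length n-2
    vbar = max(float(speed.mean()), _SPEED_EPS)
    relacc = np.diff(speed) / (dt * vbar)              # length n-2
    angacc = np.diff(angvel) / dt                      # length n-3

    L = angacc.size
    return FrameFeatures(
        speed=speed[1:L + 1],
        heading=heading[1:L + 1],
        angular_velocity=angvel[:L],
        relative_acceleration=relacc[:L],
        angular_acceleration=angacc,
    )


@dataclass
class TumbleModel:
    """Two-state HMM over (relative acceleration, |angular acceleration|).

    State 0 is "swimming", state 1 is "tumbling"; the tumbling state is the
    one with the larger mean |angular acceleration|.
    """

    transition_matrix: np.ndarray   # 2×2 row-stochastic
    means: np.ndarray               # 2×2 emission means
    covariances: np.ndarray         # 2×2×2 emission covariances
    initial_probs: np.ndarray       # length 2

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.means = np.asarray(self.means, float)
        self.covariances = np.asarray(self.covariances, float)
        self.initial_probs = np.asarray(self.initial_probs, float)
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        for c in self.covariances:
            if not np.allclose(c, c.T, atol=1e-9) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be symmetric positive-definite")

    def _as_hmm(self) -> GaussianHMM:
        hmm = GaussianHMM(n_components=2, covariance_type="full", init_params="")
        hmm.startprob_ = self.initial_probs
        hmm.transmat_ = self.transition_matrix
        hmm.means_ = self.means
        hmm.covars_ = self.covariances
        return hmm


def _pool_features(tracks: TrackSet) -> Tuple[np.ndarray, list]:
    X, lengths = [], []
    for traj in tracks:
        if traj.n_points < 4:
            continue
        m = compute_frame_features(traj).matrix()
        X.append(m)
        lengths.append(m.shape[0])
    if not X:
        raise ValueError("no trajectory long enough to extract features")
    return np.concatenate(X), lengths


def train_tumble_model(reference: TrackSet, n_iter: int = 500,
                       tol_per_frame: float = 1e-6, seed: int = 0) -> TumbleModel:
    """Fit the two-state tumble HMM on pooled features by Baum–Welch.

    The reference set should contain both smooth runs and reorientation
    events (e.g. simulated wild-type-like tracks with finite-duration
    tumbles).  States are labeled afterwards: "tumbling" is the state with
    the larger mean |angular acceleration|.  Training is invariant to
    trajectory order because features are pooled.
    """
    X, lengths = _pool_features(reference)
    # deterministic, data-driven initialization: split frames at the 90th
    # percentile of |angular acceleration| so the rare-jerk state starts small
    thr = np.quantile(X[:, 1], 0.90)
    lab = (X[:, 1] > thr).astype(int)
    means0 = np.array([X[lab == s].mean(axis=0) for s in (0, 1)])
    covs0 = []
    for s in (0, 1):
        c = np.cov(X[lab == s].T)
        c = np.atleast_2d(c) + np.eye(2) * 1e-8
        covs0.append(c)

    hmm = GaussianHMM(n_components=2, covariance_type="full",
                      n_iter=n_iter, tol=tol_per_frame * X.shape[0],
                      init_params="", params="stmc",
                      random_state=seed, min_covar=1e-8)
    hmm.startprob_ = np.array([0.95, 0.05])
    hmm.transmat_ = np.array([[0.95, 0.05], [0.30, 0.70]])
    hmm.means_ = means0
    hmm.covars_ = np.array(covs0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(X, lengths)

    means = hmm.means_
    covs = hmm.covars_ + np.eye(2) * 1e-12
    trans = hmm.transmat_
    start = hmm.startprob_
    # label: tumbling = larger mean |angular acceleration|
    if means[0, 1] > means[1, 1]:
        order = [1, 0]
        means = means[order]
        covs = covs[order]
        trans = trans[np.ix_(order, order)]
        start = start[order]
    elif means[0, 1] == means[1, 1]:
        log.warning("degenerate emission means; keeping state 0 as swimming")
    return TumbleModel(transition_matrix=trans, means=means,
                       covariances=covs, initial_probs=np.clip(start, 1e-12, None)
                       / max(start.sum(), 1e-12))


def classify_tumbles(traj: Trajectory, model: TumbleModel, halo: int = 1):
    """Viterbi state path and tumble bias for one trajectory.

    The raw Viterbi path over-extends each tumbling run by about one frame
    per side: the emission features are finite differences, so a state change
    at frame k contaminates features at k ± 1.  Each decoded run is therefore
    eroded by ``halo`` frames per side (the stencil radius of the
    angular-acceleration feature; a run never shrinks below one frame).

    Returns ``(states, tumble_bias, events)`` where ``states`` is the 0/1
    (swim/tumble) path over interior frames, ``tumble_bias`` the fraction of
    frames labeled tumbling, and ``events`` a list of (start_idx, end_idx)
    maximal tumbling runs (end exclusive).
    """
    X = compute_frame_features(traj).matrix()
    hmm = model._as_hmm()
    raw = hmm.predict(X)
    if raw.shape[0] != X.shape[0]:
        raise RuntimeError("state/feature length mismatch")
    runs = []
    in_run = False
    for i, s in enumerate(raw):
        if s == 1 and not in_run:
            start = i
            in_run = True
        elif s == 0 and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(raw)))
    events = []
    for a, b in runs:
        a2, b2 = a + halo, b - halo
        if a2 >= b2:            # short run: keep its central frame
            mid = (a + b) // 2
            a2, b2 = mid, mid + 1
        events.append((a2, b2))
    states = np.zeros_like(raw)
    for a, b in events:
        states[a:b] = 1
    tumble_bias = float(states.mean())
    return states, tumble_bias, events


def estimate_diffusion_cve(traj: Trajectory, resample_interval: float = 10.0):
    """Covariance-based estimate of the effective diffusion coefficient.

    The trajectory is subsampled at interval Δ (default 10 s, beyond the
    rotational-diffusion timescale so the motion is diffusive); per axis
    D̂ = ⟨δ²⟩/(2Δ) + ⟨δₙδₙ₊₁⟩/Δ with δ the subsampled displacements, and the
    two axes are averaged.  The adjacent-displacement covariance term cancels
    static localization noise.  For a 100 s track there are only ~10
    subsampled points, so single-track estimates are noisy and may be
    negative; negative values are returned as-is (``flagged=True``).

    Returns ``(D, flagged)``.
    """
    if resample_interval <= 0:
        raise ValueError("resample_interval must be > 0")
    if traj.duration < 3 * resample_interval:
        raise ValueError("track shorter than 3 × resample_interval")
    stride = max(1, int(round(resample_interval / traj.dt)))
    delta = stride * traj.dt
    xs = traj.x[::stride]
    ys = traj.y[::stride]
    D_axes = []
    for p in (xs, ys):
        d = np.diff(p)
        var_term = np.mean(d**2) / (2 * delta)
        cov_term = np.mean(d[:-1] * d[1:]) / delta if d.size >= 2 else 0.0
        D_axes.append(var_term + cov_term)
    D = float(np.mean(D_axes))
    return D, D < 0


def directional_persistence(D: float, v0: float) -> float:
    """Directional persistence τ from D = ½ v₀² τ, i.e. τ = 2D/v₀².

    A negative D (noisy short-track CVE) yields a negative τ, passed through.
    """
    if v0 <= 0:
        raise ValueError("persistence undefined for v0 <= 0")
    tau = 2.0 * D / v0**2
    if tau < 0:
        log.warning("negative persistence τ=%.3g s from negative D", tau)
    return tau


def summarize_population(tracks: TrackSet, model: Optional[TumbleModel] = None,
                         min_duration: float = 10.0, min_speed: float = 5.0,
                         resample_interval: float = 10.0) -> pd.DataFrame:
    """Per-cell TrajectoryStats table for a population of tracks.

    Cells shorter than ``min_duration`` (s) or slower than ``min_speed``
    (μm/s mean frame speed) are excluded as non-motile.  Columns:
    cell_id, v0_um_s, tumble_bias, D_um2_s, tau_s, duration_s.
    Pass ``model=None`` to skip tumble classification (tumble_bias = NaN).
    """
    rows = []
    for traj in tracks:
        if traj.duration < min_duration or traj.n_points < 5:
            continue
        feats = compute_frame_features(traj)
        v0 = float(feats.speed.mean())
        if v0 < min_speed:
            continue
        if model is not None:
            _, tb, _ = classify_tumbles(traj, model)
        else:
            tb = np.nan
        try:
            D, _ = estimate_diffusion_cve(traj, resample_interval)
            tau = directional_persistence(D, v0)
        except ValueError:
            D, tau = np.nan, np.nan
        rows.append(dict(cell_id=traj.cell_id, v0_um_s=v0, tumble_bias=tb,
                         D_um2_s=D, tau_s=tau, duration_s=traj.duration))
    if not rows:
        log.warning("summarize_population: no track passed the filters")
        return pd.DataFrame(columns=["cell_id", "v0_um_s", "tumble_bias",
                                     "D_um2_s", "tau_s", "duration_s"])
    return pd.DataFrame(rows)


def population_distributions(stats: pd.DataFrame) -> dict:
    """Pooled mean/median summaries of the per-cell statistics table."""
    out = {}
    for col in ("v0_um_s", "tumble_bias", "D_um2_s", "tau_s"):
        vals = stats[col].dropna().to_numpy()
        out[col] = {"mean": float(np.mean(vals)) if vals.size else np.nan,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "n": int(vals.size)}
    return out
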