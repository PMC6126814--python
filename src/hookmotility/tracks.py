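"""Trajectory containers shared by the simulator and the analysis modules.

A :class:`Trajectory` is one cell's timestamped planar positions (μm, s) on a
uniform time grid.  A :class:`TrackSet` is a population of trajectories,
optionally carrying the generative parameters and per-cell ground truth when
the data came from the built-in simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Trajectory", "CellTruth", "TrackSet"]

_DT_ATOL = 1e-9  # s; tolerance on time-grid uniformity


@dataclass
class Trajectory:
    """One cell's positions on a uniform time grid.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, uniformly spaced.
    x, y : array of float
        Positions in μm.
    cell_id : int
        Identifier within the parent :class:`TrackSet`.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValueError("trajectory needs at least 3 time points")
        if not (self.times.size == self.x.size == self.y.size):
            raise ValueError("times, x, y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("positions must be finite")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(steps) > _DT_ATOL:
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in μm."""
        return np.column_stack([self.x, self.y])


@dataclass
class CellTruth:
    """Generative ground truth for one simulated cell."""

    psi: float = 0.0               # rad/s, signed curvature of circular motion
    speed: float = 0.0             # μm/s, tangential speed
    tumble_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    tumbling: Optional[np.ndarray] = None   # bool per frame (finite-duration mode)
    x_true: Optional[np.ndarray] = None     # unwrapped positions, μm
    y_true: Optional[np.ndarray] = None

    @property
    def n_tumbles(self) -> int:
        return int(np.asarray(self.tumble_times).size)


@dataclass
class TrackSet:
    """A population of trajectories plus optional generative metadata."""

    trajectories: list
    config: Optional[object] = None          # SimulationConfig when simulated
    ground_truth: Optional[dict] = None      # cell_id -> CellTruth

    def __post_init__(self) -> None:
        if self.trajectories:
            dts = np.array([t.dt for t in self.trajectories])
            if np.ptp(dts) > _DT_ATOL:
                raise ValueError("all trajectories in a TrackSet must share dt")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def dt(self) -> float:
        if not self.trajectories:
            raise ValueError("empty TrackSet has no dt")
        return self.trajectories[0].dt

    def unwrapped(self) -> "TrackSet":
        """TrackSet with periodic-wrap artifacts removed.

        Uses the unwrapped ground-truth coordinates where available; passes
        trajectories through unchanged otherwise (empirical data never wrap).
        """
        if not self.ground_truth:
            return self
        out = []
        for traj in self.trajectories:
            truth = self.ground_truth.get(traj.cell_id)
            if truth is not None and truth.x_true is not None:
                out.append(Trajectory(traj.times, truth.x_true, truth.y_true,
                                      cell_id=traj.cell_id))
            else:
                out.append(traj)
        return TrackSet(out, config=self.config, ground_truth=self.ground_truth)

    def subset(self, cell_ids) -> "TrackSet":
        wanted = set(cell_ids)
        trajs = [t for t in self.trajectories if t.cell_id in wanted]
        truth = None
        if self.ground_truth is not None:
            truth = {cid: ct for cid, ct in self.ground_truth.items() if cid in wanted}
        return TrackSet(trajs, config=self.config, ground_truth=truth)


def concatenate_tracksets(sets) -> TrackSet:
    """Merge TrackSets, reassigning cell ids to stay unique."""
    trajs = []
    truth = {}
    next_id = 0
    for ts in sets:
        for traj in ts.trajectories:
            new = Trajectory(traj.times, traj.x, traj.y, cell_id=next_id)
            trajs.append(new)
            if ts.ground_truth and traj.cell_id in ts.ground_truth:
                truth[next_id] = ts.ground_truth[traj.cell_id]
            next_id += 1
    return TrackSet(trajs, ground_truth=truth or None)
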