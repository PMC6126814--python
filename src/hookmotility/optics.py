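"""Virtual microscope: render track sets into phase-like or dark-field movies.

Cells are drawn as Gaussian spots of width ``psf_sigma``.  In phase mode each
cell has a constant intensity; in dark-field mode the intensity flickers as
1 + wobble_depth·sin(2π·wobble_frequency·t + φ_cell), emulating the image
flicker produced by cell-body rotation at angular velocity Ω = 2π·frequency.
Gaussian read noise is added per pixel and intensities are clipped at zero.
Rendering is periodic in the field of view (positions taken modulo the field
extent), which keeps the image sequence consistent with the simulator's
periodic box and is harmless for Fourier-domain analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracks import TrackSet

__all__ = ["OpticsConfig", "ImageStack", "render_movie"]


@dataclass
class OpticsConfig:
    """Optical parameters of the virtual microscope."""

    pixel_size: float = 0.5        # μm/px
    psf_sigma: float = 0.6         # μm, Gaussian spot width
    cell_intensity: float = 120.0  # a.u., peak amplitude per cell
    background: float = 20.0       # a.u.
    noise_sigma: float = 2.0       # a.u., per-pixel Gaussian read noise
    image_size: int = 256          # px (square)
    modality: str = "phase"        # "phase" | "darkfield"
    wobble_frequency: float = 0.0  # Hz; equals Ω/2π (dark-field mode)
    wobble_depth: float = 0.0      # fraction of cell intensity

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (0 <= self.wobble_depth <= 1):
            raise ValueError("wobble_depth must be in [0, 1]")
        if self.modality not in ("phase", "darkfield"):
            raise ValueError("modality must be 'phase' or 'darkfield'")

    @property
    def field_um(self) -> float:
        return self.image_size * self.pixel_size


@dataclass
class ImageStack:
    """Image frames plus the metadata needed for DDM/DFM analysis."""

    frames: np.ndarray             # (n_frames, ny, nx), a.u.
    pixel_size: float              # μm/px
    frame_interval: float          # s
    modality: str = "phase"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack needs >= 2 frames of uniform shape")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def render_movie(tracks: TrackSet, optics: OpticsConfig, seed: int = 0) -> ImageStack:
    """Render a TrackSet into an image stack with the given optics.

    Raises if a dark-field wobble frequency is at or above the Nyquist limit
    of the frame rate (the flicker would alias).
    """
    if tracks.trajectories:
        dt = tracks.dt
        times = tracks.trajectories[0].times
        n_frames = times.size
    else:
        dt = 0.01
        times = np.arange(2) * dt
        n_frames = 2
    if optics.modality == "darkfield" and optics.wobble_frequency > 0:
        nyquist = 1.0 / (2.0 * dt)
        if optics.wobble_frequency >= nyquist:
            raise ValueError(
                f"wobble frequency {optics.wobble_frequency} Hz aliases: "
                f"Nyquist limit is {nyquist} Hz at frame interval {dt} s")

    rng = np.random.default_rng(seed)
    n_px = optics.image_size
    field = optics.field_um
    sigma_px = optics.psf_sigma / optics.pixel_size
    half = max(2, int(math.ceil(4 * sigma_px)))
    win = np.arange(-half, half + 1)

    n_cells = len(tracks.trajectories)
    phases = rng.uniform(0, 2 * np.pi, size=n_cells)
    # per-frame multiplicative intensity factors
    if optics.modality == "darkfield" and optics.wobble_frequency > 0 and n_cells:
        factors = 1.0 + optics.wobble_depth * np.sin(
            2 * np.pi * optics.wobble_frequency * times[None, :] + phases[:, None])
    else:
        factors = np.ones((max(n_cells, 1), n_frames))

    frames = np.zeros((n_frames, n_px, n_px), dtype=np.float64)
    for ci, traj in enumerate(tracks.trajectories):
        px = np.mod(traj.x, field) / optics.pixel_size
        py = np.mod(traj.y, field) / optics.pixel_size
        ix = np.floor(px).astype(int)
        iy = np.floor(py).astype(int)
        for k in range(n_frames):
            gx = np.exp(-0.5 * ((win + ix[k] - px[k]) / sigma_px) ** 2)
            gy = np.exp(-0.5 * ((win + iy[k] - py[k]) / sigma_px) ** 2)
            stamp = (optics.cell_intensity * factors[ci, k]) * np.outer(gy, gx)
            rows = np.mod(win + iy[k], n_px)
            cols = np.mod(win + ix[k], n_px)
            frames[k][np.ix_(rows, cols)] += stamp

    frames += optics.background
    if optics.noise_sigma > 0:
        frames += rng.normal(0, optics.noise_sigma, size=frames.shape)
    np.clip(frames, 0, None, out=frames)
    return ImageStack(frames=frames.astype(np.float32), pixel_size=optics.pixel_size,
                      frame_interval=dt, modality=optics.modality)
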