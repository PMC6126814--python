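"""Differential dynamic microscopy: structure function and swimming-ISF fits.

DDM characterizes population motility from the spatiotemporal decorrelation
of low-resolution movies.  The image structure function
g(q,τ) = ⟨|Î(q, t+τ) − Î(q, t)|²⟩ (radially averaged over q orientations)
relates to the intermediate scattering function f(q,τ) through
g = A(q)·[1 − f(q,τ)] + B(q), with A the signal amplitude and B the camera
noise floor.  For a mixed population of swimmers (fraction α) and diffusers,

    f(q,τ) = (1−α)·e^{−Dq²τ} + α·e^{−Dq²τ}·Ws(q·v̄·τ; Z)

where Ws is the orientation-averaged swimming term for a Schulz speed
distribution of mean v̄ and width σ, Z = (v̄/σ)² − 1:

    Ws(x; Z) = (Z+1)/(Z·x) · sin(Z·atan(x/(Z+1))) / (1 + (x/(Z+1))²)^{Z/2}

which reduces to sinc(x) = sin(x)/x as σ → 0.  Fitted speeds are summarized
over the band 0.5 ≤ q ≤ 2 μm⁻¹ (length scales L = 2π/q of 3–13 μm), and the
path-straightness ratio R = v(L1)/v(L2) equals 1 for straight swimmers,
rising above 1 when tumbling or rotational diffusion bends trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .optics import ImageStack

__all__ = [
    "StructureFunction",
    "ISFFit",
    "DDMResult",
    "schulz_swimming_term",
    "image_structure_function",
    "fit_isf",
    "ddm_summary",
]

log = logging.getLogger(__name__)

MIN_MODES_PER_BIN = 8


@dataclass
class StructureFunction:
    """Radially averaged image structure function g(q, τ)."""

    q: np.ndarray            # μm⁻¹, bin centers
    tau: np.ndarray          # s
    g: np.ndarray            # (n_q, n_tau), a.u.
    n_modes: np.ndarray      # Fourier modes per q bin
    pixel_size: float
    frame_interval: float


@dataclass
class ISFFit:
    """Per-q parameters of the swimming ISF model."""

    q: np.ndarray
    A: np.ndarray
    B: np.ndarray
    D: np.ndarray            # μm²/s
    v: np.ndarray            # μm/s
    sigma: np.ndarray        # μm/s
    alpha: np.ndarray        # swimming fraction
    residual: np.ndarray     # RMS residual / A
    ok: np.ndarray           # bool, fit accepted


@dataclass
class DDMResult:
    """Band-averaged DDM motility summary."""

    v: float                 # μm/s
    sigma: float             # μm/s
    S: float                 # σ/v
    R: float                 # v(L1)/v(L2)
    q_window: Tuple[float, float]
    L1: float
    L2: float
    q_L1: float = np.nan     # q bins actually used for R
    q_L2: float = np.nan


def schulz_swimming_term(x, Z: float):
    """Orientation-averaged ISF swimming factor for a Schulz speed law.

    Ws(x; Z) with x = q·v̄·τ; Ws → sinc(x) as Z → ∞ (σ → 0).
    """
    x = np.asarray(x, float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    xz = x[nz]
    a = xz / (Z + 1.0)
    out[nz] = ((Z + 1.0) / (Z * xz) * np.sin(Z * np.arctan(a))
               / (1.0 + a**2) ** (Z / 2.0))
    return out


def image_structure_function(stack: ImageStack,
                             tau_frames: Optional[Sequence[int]] = None,
                             max_averages: int = 200) -> StructureFunction:
    """Compute g(q,τ) by Fourier-differencing the movie.

    g(q,τ) is the time average of |FFT2(I(t+τ)) − FFT2(I(t))|², radially
    averaged into annular q bins one FFT pixel wide (bins with fewer than
    8 modes are dropped).  q = 2π × spatial frequency, in μm⁻¹.  ``tau_frames``
    defaults to ~40 log-spaced frame lags up to a quarter of the movie;
    at most ``max_averages`` start frames are used per lag.
    """
    frames = stack.frames
    n_frames, ny, nx = frames.shape
    if tau_frames is None:
        upper = max(n_frames // 4, 1)
        tau_frames = np.unique(np.round(np.geomspace(1, upper, 40)).astype(int))
    tau_frames = np.asarray(sorted(set(int(t) for t in tau_frames)))
    if tau_frames[0] < 1 or tau_frames[-1] >= n_frames:
        raise ValueError("tau_frames must lie in [1, n_frames)")

    fts = np.fft.rfft2(frames).astype(np.complex64)

    qx = 2 * np.pi * np.fft.rfftfreq(nx, d=stack.pixel_size)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=stack.pixel_size)
    qmag = np.hypot(qy[:, None], qx[None, :])
    # rfft half-plane: interior columns stand for a conjugate pair of modes
    wt = np.full((ny, qx.size), 2.0)
    wt[:, 0] = 1.0
    if nx % 2 == 0:
        wt[:, -1] = 1.0

    dq = 2 * np.pi / (max(nx, ny) * stack.pixel_size)
    bin_idx = np.round(qmag / dq).astype(int)
    n_bins = bin_idx.max() + 1
    mode_counts = np.bincount(bin_idx.ravel(), weights=wt.ravel(), minlength=n_bins)

    g = np.zeros((n_bins, tau_frames.size))
    flat_idx = bin_idx.ravel()
    flat_wt = wt.ravel()
    for j, tau in enumerate(tau_frames):
        starts = np.arange(0, n_frames - tau)
        if starts.size > max_averages:
            starts = starts[np.linspace(0, starts.size - 1, max_averages).astype(int)]
        acc = np.zeros(n_bins)
        for t0 in starts:
            diff = fts[t0 + tau] - fts[t0]
            power = (diff.real.astype(np.float64)**2 + diff.imag.astype(np.float64)**2)
            acc += np.bincount(flat_idx, weights=power.ravel() * flat_wt,
                               minlength=n_bins)
        g[:, j] = acc / (starts.size * np.maximum(mode_counts, 1))

    keep = (mode_counts >= MIN_MODES_PER_BIN) & (np.arange(n_bins) > 0)
    q_centers = np.arange(n_bins) * dq
    return StructureFunction(q=q_centers[keep], tau=tau_frames * stack.frame_interval,
                             g=g[keep], n_modes=mode_counts[keep],
                             pixel_size=stack.pixel_size,
                             frame_interval=stack.frame_interval)


def _isf_model(tau, q, p):
    A, B, D, v, S, alpha = p
    Z = 1.0 / S**2 - 1.0
    envelope = np.exp(-D * q**2 * tau)
    f = envelope * ((1 - alpha) + alpha * schulz_swimming_term(q * v * tau, Z))
    return A * (1.0 - f) + B


def fit_isf(sf: StructureFunction, q_range: Tuple[float, float] = (0.3, 2.5),
            v_starts: Sequence[float] = (5.0, 15.0, 30.0)) -> ISFFit:
    """Fit the swimming ISF model to g(q,τ) independently at each q.

    Bounded least squares over (A, B, D, v̄, S, α) with multistart on v̄;
    A and B are initialized from the long-τ plateau and the short-τ floor.
    A q bin whose best fit keeps more than 15% RMS residual relative to A is
    flagged not-ok and excluded from downstream band averages.
    """
    sel = (sf.q >= q_range[0]) & (sf.q <= q_range[1])
    if sf.tau.size < 20:
        raise ValueError("need >= 20 tau points to fit the ISF")
    qs = sf.q[sel]
    gsel = sf.g[sel]
    n = qs.size
    out = {k: np.full(n, np.nan) for k in ("A", "B", "D", "v", "sigma", "alpha",
                                           "residual")}
    ok = np.zeros(n, bool)
    tau = sf.tau
    for i, (qv, gq) in enumerate(zip(qs, gsel)):
        plateau = float(np.mean(gq[tau >= np.quantile(tau, 0.75)]))
        floor = float(max(np.min(gq), 0.0))
        A0 = max(plateau - floor, 1e-6)
        lo = [A0 * 0.05, 0.0, 0.0, 0.5, 0.02, 0.0]
        hi = [A0 * 20.0, max(floor * 10.0, A0), 50.0, 200.0, 0.95, 1.0]
        best = None
        for v0 in v_starts:
            p0 = np.clip([A0, floor + 1e-9, 0.3, v0, 0.2, 0.9], lo, hi)
            try:
                res = least_squares(lambda p: _isf_model(tau, qv, p) - gq, p0,
                                    bounds=(lo, hi), max_nfev=2000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            log.warning("ISF fit failed at q=%.3f", qv)
            continue
        A, B, D, v, S, alpha = best.x
        rms = float(np.sqrt(np.mean((_isf_model(tau, qv, best.x) - gq)**2)) / A)
        out["A"][i], out["B"][i], out["D"][i] = A, B, D
        out["v"][i], out["sigma"][i], out["alpha"][i] = v, S * v, alpha
        out["residual"][i] = rms
        ok[i] = rms < 0.15
        if not ok[i]:
            log.warning("ISF fit at q=%.3f rejected (relative RMS %.3f)", qv, rms)
    return ISFFit(q=qs, A=out["A"], B=out["B"], D=out["D"], v=out["v"],
                  sigma=out["sigma"], alpha=out["alpha"],
                  residual=out["residual"], ok=ok)


def ddm_summary(fit: ISFFit, q_window: Tuple[float, float] = (0.5, 2.0),
                L1: float = 3.0, L2: float = 13.0) -> DDMResult:
    """Band-averaged speed statistics and the path-straightness ratio R.

    v and σ are means of the per-q fits over ``q_window``; R = v(L1)/v(L2)
    uses the accepted q bins nearest 2π/L1 and 2π/L2 (no interpolation).
    """
    good = fit.ok & np.isfinite(fit.v)
    in_win = good & (fit.q >= q_window[0]) & (fit.q <= q_window[1])
    if not in_win.any():
        raise ValueError("no accepted ISF fits inside the q window")
    v = float(np.mean(fit.v[in_win]))
    sigma = float(np.mean(fit.sigma[in_win]))
    qg = fit.q[good]
    vg = fit.v[good]
    i1 = int(np.argmin(np.abs(qg - 2 * np.pi / L1)))
    i2 = int(np.argmin(np.abs(qg - 2 * np.pi / L2)))
    log.info("R uses q=%.3f (L1=%.1f μm) and q=%.3f (L2=%.1f μm)",
             qg[i1], L1, qg[i2], L2)
    R = float(vg[i1] / vg[i2])
    return DDMResult(v=v, sigma=sigma, S=sigma / v, R=R, q_window=q_window,
                     L1=L1, L2=L2, q_L1=float(qg[i1]), q_L2=float(qg[i2]))
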