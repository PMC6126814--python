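"""Circular run-and-tumble model: closed forms, empirical estimators, fitting.

Near a surface, a swimming cell's run is a circular arc of radius s traversed
at angular velocity ψ (tangential speed v = ψ·s).  For a single cell the
orientational autocorrelation is cos(ψt) and the mean square displacement is
2s²[1 − cos(ψt)].  Averaging the autocorrelation over a population with
ψ ~ Exponential(λ) gives λ²/(λ² + t²).  Adding tumbles — complete, uniform
reorientation at exponentially distributed waiting times of rate λ_T —
multiplies the single-cell autocorrelation by the survival probability of a
run, yielding e^{−λ_T t}·cos(ψt); this form is verified against a Monte-Carlo
ensemble of the simulator in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .tracks import TrackSet, Trajectory

__all__ = [
    "CircularRTParams",
    "CorrelationCurve",
    "acf_circular",
    "msd_circular",
    "acf_population_exponential",
    "acf_circular_rt",
    "empirical_acf",
    "empirical_msd",
    "fit_circular_rt",
]

log = logging.getLogger(__name__)


@dataclass
class CircularRTParams:
    """Parameters of the circular run-and-tumble model."""

    psi: float                      # rad/s
    s: float                        # μm, circle radius
    v: float                        # μm/s, tangential speed (v = ψ·s)
    tumble_rate: float = 0.0        # 1/s
    psi_lambda: Optional[float] = None  # 1/(rad/s), population mode

    def __post_init__(self) -> None:
        if self.psi < 0 or self.s < 0:
            raise ValueError("psi and s must be >= 0")
        if self.psi > 0 and self.s > 0:
            if abs(self.v - self.psi * self.s) > 1e-9 * max(self.v, 1e-12):
                raise ValueError("v must equal psi*s")


@dataclass
class CorrelationCurve:
    """Empirical ACF (dimensionless) or MSD (μm²) on a lag grid."""

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray = field(default=None)
    kind: str = "acf"               # "acf" | "msd"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.n_pairs is None:
            self.n_pairs = np.ones_like(self.lags)
        self.n_pairs = np.asarray(self.n_pairs, float)
        if np.any(np.diff(self.lags) <= 0) or self.lags[0] < 0:
            raise ValueError("lags must be nonnegative and increasing")


# ---------------------------------------------------------------- closed forms

def acf_circular(t, psi: float):
    """Orientational autocorrelation of uniform circular motion: cos(ψt)."""
    return np.cos(psi * np.asarray(t, float))


def msd_circular(t, s_radius: float, psi: float):
    """MSD of uniform circular motion: 2s²[1 − cos(ψt)].

    The short-time expansion is (ψs)²t² = v²t² (ballistic), and the curve is
    bounded by the squared diameter 4s².
    """
    return 2.0 * s_radius**2 * (1.0 - np.cos(psi * np.asarray(t, float)))


def acf_population_exponential(t, lam: float):
    """Population-averaged autocorrelation for ψ ~ Exponential(λ).

    ∫₀^∞ cos(ψt)·λe^{−λψ} dψ = λ²/(λ² + t²): a Lorentzian decay that never
    crosses zero, in contrast with the single-ψ cosine.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    t = np.asarray(t, float)
    return lam**2 / (lam**2 + t**2)


def acf_circular_rt(t, psi: float, tumble_rate: float):
    """Autocorrelation with tumbles: e^{−λ_T t}·cos(ψt).

    Runs survive to lag t with probability e^{−λ_T t}; a tumble reorients
    uniformly, so correlation after any tumble averages to zero, leaving the
    circular cos(ψt) weighted by the survival probability.
    """
    if tumble_rate < 0:
        raise ValueError("tumble_rate must be >= 0")
    t = np.asarray(t, float)
    return np.exp(-tumble_rate * t) * np.cos(psi * t)


# ------------------------------------------------------------------ estimators

def _as_trajs(data) -> list:
    if isinstance(data, Trajectory):
        return [data]
    return list(data)


def empirical_acf(data: Union[Trajectory, TrackSet], max_lag: float) -> CorrelationCurve:
    """Time- and ensemble-averaged orientational autocorrelation.

    Unit heading vectors ĉ come from frame displacements; ACF(kΔ) is the mean
    over start times and cells of ĉ(t)·ĉ(t+kΔ).  Displacements shorter than
    numerical zero contribute nothing (their heading is undefined).
    """
    trajs = _as_trajs(data)
    dt = trajs[0].dt
    max_avail = max(t.duration for t in trajs) - dt
    if max_lag > max_avail:
        log.warning("max_lag %.3g s exceeds data span; truncating", max_lag)
        max_lag = max_avail
    n_lags = int(np.floor(max_lag / dt)) + 1
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags)
    for traj in trajs:
        dx = np.diff(traj.x)
        dy = np.diff(traj.y)
        norm = np.hypot(dx, dy)
        ok = norm > 1e-12
        ux = np.where(ok, dx / np.where(ok, norm, 1.0), 0.0)
        uy = np.where(ok, dy / np.where(ok, norm, 1.0), 0.0)
        m = ux.size
        for k in range(min(n_lags, m)):
            dots = ux[:m - k] * ux[k:] + uy[:m - k] * uy[k:]
            valid = ok[:m - k] & ok[k:]
            sums[k] += dots[valid].sum()
            counts[k] += valid.sum()
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lags = np.arange(n_lags) * dt
    return CorrelationCurve(lags=lags, values=values, n_pairs=counts, kind="acf")


def empirical_msd(data: Union[Trajectory, TrackSet], max_lag: float) -> CorrelationCurve:
    """Time- and ensemble-averaged mean square displacement ⟨|r(t+τ)−r(t)|²⟩.

    For simulated TrackSets the unwrapped ground-truth coordinates are used,
    so periodic-box wraps never inflate the MSD.
    """
    if isinstance(data, TrackSet):
        data = data.unwrapped()
    trajs = _as_trajs(data)
    dt = trajs[0].dt
    max_avail = max(t.duration for t in trajs)
    if max_lag > max_avail:
        log.warning("max_lag %.3g s exceeds data span; truncating", max_lag)
        max_lag = max_avail
    n_lags = int(np.floor(max_lag / dt)) + 1
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags)
    for traj in trajs:
        x, y = traj.x, traj.y
        n = x.size
        for k in range(min(n_lags, n)):
            d2 = (x[k:] - x[:n - k])**2 + (y[k:] - y[:n - k])**2
            sums[k] += d2.sum()
            counts[k] += d2.size
    values = sums / np.maximum(counts, 1)
    lags = np.arange(n_lags) * dt
    return CorrelationCurve(lags=lags, values=values, n_pairs=counts, kind="msd")


# --------------------------------------------------------------------- fitting

@dataclass
class RTFitResult:
    params: CircularRTParams
    residual_rms: float
    fitted_acf: np.ndarray
    mode: str                      # "single" | "population"


def _speed_from_msd(msd: CorrelationCurve, robust: bool = False) -> float:
    """Tangential speed from the short-time ballistic limit of the MSD.

    v = sqrt(MSD(Δ))/Δ from the first nonzero lag; with ``robust=True`` a
    quadratic a·τ² is fitted through the origin using the first 3 points.
    """
    nz = msd.lags > 0
    lags = msd.lags[nz]
    vals = msd.values[nz]
    if robust and lags.size >= 3:
        a = float(np.sum(vals[:3] * lags[:3]**2) / np.sum(lags[:3]**4))
        return float(np.sqrt(max(a, 0.0)))
    return float(np.sqrt(max(vals[0], 0.0)) / lags[0])


def fit_circular_rt(acf: CorrelationCurve, msd: CorrelationCurve,
                    population: bool = False, max_lag: Optional[float] = None,
                    n_starts: int = 20, robust_speed: bool = False) -> RTFitResult:
    """Fit the circular run-and-tumble model to empirical ACF and MSD curves.

    ψ and the tumble rate come from weighted least squares of
    e^{−λ_T t}cos(ψt) (or, in population mode, e^{−λ_T t}·λ²/(λ²+t²)) against
    the empirical ACF; v comes from the first MSD point assuming ballistic
    short-time motion; s = v/ψ.  Lags are weighted by sqrt(n_pairs) to
    downweight noisy long lags.  ψ is multistarted on [0, π/Δ].
    """
    mask = np.isfinite(acf.values) & (acf.n_pairs > 0)
    if max_lag is not None:
        mask &= acf.lags <= max_lag
    t = acf.lags[mask]
    y = acf.values[mask]
    w = np.sqrt(acf.n_pairs[mask])
    if t.size < 10:
        raise ValueError("need at least 10 ACF lags to fit")
    dt = np.min(np.diff(acf.lags))
    psi_max = np.pi / dt

    def model(p):
        if population:
            return np.exp(-p[1] * t) * acf_population_exponential(t, p[0])
        return acf_circular_rt(t, p[0], p[1])

    def resid(p):
        return w * (model(p) - y)

    best = None
    if population:
        starts = [(lam0, r0) for lam0 in np.geomspace(0.1, 10, max(n_starts // 2, 2))
                  for r0 in (0.1, 1.0)]
        bounds = ([1e-6, 0.0], [np.inf, np.inf])
    else:
        starts = [(p0, r0) for p0 in np.linspace(0.0, psi_max * 0.9, max(n_starts // 2, 2))
                  for r0 in (0.1, 1.0)]
        bounds = ([0.0, 0.0], [psi_max, np.inf])
    for p0 in starts:
        try:
            res = least_squares(resid, x0=np.asarray(p0, float), bounds=bounds)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("circular run-and-tumble fit failed to converge")

    v = _speed_from_msd(msd, robust=robust_speed)
    if population:
        lam, rate = best.x
        psi_eff = 1.0 / lam          # mean ψ of Exponential(λ)
        params = CircularRTParams(psi=psi_eff, s=v / psi_eff if psi_eff > 0 else 0.0,
                                  v=v, tumble_rate=rate, psi_lambda=lam)
    else:
        psi, rate = best.x
        s = v / psi if psi > 0 else 0.0
        params = CircularRTParams(psi=psi, s=s, v=v, tumble_rate=rate)
    rms = float(np.sqrt(np.mean((model(best.x) - y)**2)))
    return RTFitResult(params=params, residual_rms=rms,
                       fitted_acf=model(best.x), mode="population" if population
                       else "single")
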