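"""Dark-field flicker microscopy: body angular velocity from intensity flicker.

The rotating flagellar bundle wobbles the cell body, which modulates the
dark-field image intensity of each cell at the body rotation frequency.
Segmenting cells on the temporal-mean image, Fourier-transforming each
cell's integrated-intensity time series, and averaging the power spectra
across cells yields a spectrum whose lowest-frequency peak sits at Ω/2π,
with Ω the population-averaged body angular velocity.  The processivity
P = v/Ω is the distance advanced per radian of body rotation (the average
run length per revolution is 2π·P).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .optics import ImageStack

__all__ = [
    "FlickerSpectrum",
    "DFMResult",
    "MotilitySummary",
    "flicker_spectrum",
    "body_angular_velocity",
    "processivity",
]

log = logging.getLogger(__name__)


@dataclass
class FlickerSpectrum:
    """Cell-averaged one-sided power spectrum of intensity flicker."""

    frequencies: np.ndarray   # Hz (DC excluded)
    power: np.ndarray         # a.u.
    n_cells: int


@dataclass
class DFMResult:
    Omega: float              # rad/s
    peak_frequency: float     # Hz
    spectrum: FlickerSpectrum


@dataclass
class MotilitySummary:
    """Population motility metrics; ``normalized_to`` rescales to a reference."""

    v: float                  # μm/s
    Omega: float              # rad/s
    P: float                  # μm/rad, processivity v/Ω

    def normalized_to(self, ref: "MotilitySummary") -> "MotilitySummary":
        return MotilitySummary(v=self.v / ref.v, Omega=self.Omega / ref.Omega,
                               P=self.P / ref.P)


def flicker_spectrum(stack: ImageStack, min_area: int = 4,
                     min_frames: int = 256) -> FlickerSpectrum:
    """Average per-cell power spectrum of integrated-intensity flicker.

    Cells are segmented by Otsu threshold on the temporal-mean image
    (connected regions of at least ``min_area`` px); each cell's integrated
    intensity is mean-subtracted, Hann-windowed and Fourier transformed, and
    the one-sided power spectra are averaged across cells.
    """
    if stack.modality != "darkfield":
        raise ValueError("flicker spectroscopy needs a dark-field stack")
    if stack.n_frames < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {stack.n_frames}")
    mean_img = stack.frames.mean(axis=0)
    thr = threshold_otsu(mean_img)
    labels = label(mean_img > thr)
    regions = [r for r in regionprops(labels) if r.area >= min_area]
    if not regions:
        raise ValueError("no cells found by segmentation")
    if len(regions) < 10:
        log.warning("only %d cells segmented; spectrum will be noisy", len(regions))

    n = stack.n_frames
    window = np.hanning(n)
    freqs = np.fft.rfftfreq(n, d=stack.frame_interval)
    psum = np.zeros(freqs.size)
    for r in regions:
        mask = labels == r.label
        series = stack.frames[:, mask].sum(axis=1).astype(np.float64)
        series -= series.mean()
        spec = np.abs(np.fft.rfft(series * window)) ** 2
        psum += spec
    power = psum / len(regions)
    return FlickerSpectrum(frequencies=freqs[1:], power=power[1:],
                           n_cells=len(regions))


def body_angular_velocity(spectrum: FlickerSpectrum,
                          prominence_frac: float = 0.05,
                          min_snr: float = 8.0,
                          background_win: int = 31) -> DFMResult:
    """Body angular velocity Ω = 2π·f_peak from the flicker spectrum.

    f_peak is the lowest-frequency local maximum whose prominence above a
    median-filtered background exceeds both ``prominence_frac`` of the
    largest excess and ``min_snr`` robust standard deviations of the excess
    (so pure-noise spectra yield no peak); harmonics at higher frequency are
    ignored by construction.
    """
    power = spectrum.power
    background = median_filter(power, size=min(background_win, power.size | 1),
                               mode="nearest")
    excess = power - background
    top = float(np.max(excess))
    noise = 1.4826 * float(np.median(np.abs(excess - np.median(excess))))
    if top <= 0 or top < min_snr * noise:
        raise ValueError("no spectral peak above the noise floor")
    peaks, _ = find_peaks(excess, prominence=max(prominence_frac * top,
                                                 min_snr * noise))
    if peaks.size == 0:
        raise ValueError("no qualifying spectral peak found")
    f_peak = float(spectrum.frequencies[peaks[0]])
    return DFMResult(Omega=2 * np.pi * f_peak, peak_frequency=f_peak,
                     spectrum=spectrum)


def processivity(v: float, Omega: float,
                 reference: Optional[MotilitySummary] = None) -> MotilitySummary:
    """Processivity P = v/Ω (μm per radian of body rotation).

    With ``reference`` given, the returned summary is normalized to it
    (reference values map to 1).
    """
    if Omega <= 0:
        raise ValueError("Omega must be > 0")
    out = MotilitySummary(v=v, Omega=Omega, P=v / Omega)
    if reference is not None:
        out = out.normalized_to(reference)
    return out
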