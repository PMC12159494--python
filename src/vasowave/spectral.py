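"""Amplitude spectra and fractional band amplitude (fALFF).

fALFF is the amplitude of fluctuations inside a band of interest
(default 0.08–0.15 Hz, the vasomotion band) as a fraction of the
amplitude over the whole positive-frequency range.  Following the
REST-toolbox lineage the default ratio is over one-sided DFT
*amplitudes*; a squared-amplitude (power) ratio is available via
``SpectralConfig(power_ratio=True)``.

Spectra are one-sided DFT amplitudes with DC excluded, scaled so a
unit-amplitude sinusoid at a bin frequency has amplitude ≈ 1
(``2|X_k|/N``; the Nyquist bin, when present, is not doubled).  With
this scaling Parseval's theorem reads ``var(x) = Σ A_k²/2`` for interior
bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .core import BandSpec, Movie, WAVE_BAND
from .atlas import RoiAtlas
from .preproc import roi_timecourses

__all__ = ["SpectralConfig", "Spectrum", "amplitude_spectrum", "falff", "falff_map"]


@dataclass(frozen=True)
class SpectralConfig:
    band: BandSpec = WAVE_BAND
    falff_map_threshold: float = 0.075
    detrend: bool = True
    power_ratio: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.falff_map_threshold <= 1):
            raise ValueError("falff_map_threshold must be in (0, 1]")


@dataclass
class Spectrum:
    """One-sided amplitude spectrum (DC excluded)."""

    freqs: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def peak_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.amplitude))])


def amplitude_spectrum(series: np.ndarray, dt: float, detrend: bool = True) -> Spectrum:
    """One-sided DFT amplitude spectrum of a 1-D series, DC excluded."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < 16:
        raise ValueError(f"series too short for a spectrum: {len(x)} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    if detrend:
        x = _sig.detrend(x, type="linear")
    n = len(x)
    amp = np.abs(np.fft.rfft(x)) * (2.0 / n)
    if n % 2 == 0:
        amp[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=dt)
    return Spectrum(freqs[1:], amp[1:])


def _amplitudes_nd(x: np.ndarray, detrend: bool) -> np.ndarray:
    """|rfft| amplitudes along the last axis, DC excluded (no 2/N scaling —
    it cancels in the fALFF ratio)."""
    if detrend:
        x = _sig.detrend(x, type="linear", axis=-1)
    return np.abs(np.fft.rfft(x, axis=-1))[..., 1:]


def _band_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    mask = (freqs >= band.low) & (freqs <= band.high)
    if not mask.any():
        raise ValueError(
            f"band [{band.low}, {band.high}] Hz contains no frequency bins"
        )
    return mask


def falff(series: np.ndarray, dt: float, band: BandSpec = WAVE_BAND,
          detrend: bool = True, power_ratio: bool = False) -> float:
    """Fractional amplitude of fluctuations in ``band``.

    Sum of spectral amplitudes over the band's bins divided by the sum
    over all positive-frequency bins; always in [0, 1] and invariant to
    rescaling of the series.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 16:
        raise ValueError(f"series too short: {len(x)} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    band.validate_for(dt)
    amp = _amplitudes_nd(x, detrend)
    freqs = np.fft.rfftfreq(len(x), d=dt)[1:]
    mask = _band_mask(freqs, band)
    if power_ratio:
        amp = amp**2
    total = float(amp.sum())
    if total == 0:
        return 0.0
    return float(amp[mask].sum() / total)


def falff_map(
    movie: Movie, atlas: RoiAtlas, config: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, dict[int, float], np.ndarray]:
    """Per-pixel fALFF map, per-ROI fALFF, and the thresholded mask.

    The movie must be raw (unfiltered): no frequency filtering precedes
    fALFF extraction.  ROI values are the fALFF of the ROI-mean series
    (signal extraction before analysis), not the mean of pixel fALFFs.
    Mask is ``map > falff_map_threshold`` (0.075 by default).
    """
    config.band.validate_for(movie.spec.dt)
    h, w, n = movie.shape
    flat = movie.data.reshape(h * w, n).astype(np.float64)
    amp = _amplitudes_nd(flat, config.detrend)
    if config.power_ratio:
        amp = amp**2
    freqs = np.fft.rfftfreq(n, d=movie.spec.dt)[1:]
    mask = _band_mask(freqs, config.band)
    total = amp.sum(axis=1)
    total[total == 0] = np.inf  # constant pixel -> fALFF 0
    fmap = (amp[:, mask].sum(axis=1) / total).reshape(h, w)

    tcs = roi_timecourses(movie, atlas)
    roi_falff = {
        rid: falff(tcs.series[rid], movie.spec.dt, config.band,
                   config.detrend, config.power_ratio)
        for rid in tcs.ids()
    }
    return fmap.astype(np.float32), roi_falff, fmap > config.falff_map_threshold
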