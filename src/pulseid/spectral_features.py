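"""Smoothed 1-D spectral profiles and peak/notch extraction.

Two interchangeable feature extractors feed the classifier: the
VMD-gram energy spectrum (sum of instantaneous energies per 50 Hz bin,
log10 scale, 17-point median + 11-point moving-average smoothing) and a
conventional Welch power spectrum (2048-point Hann, 50% overlap, dB
scale, 21-point median + 15-point moving average). Peaks are local
maxima whose topographic prominence clears a threshold; notches are
peaks of the negated profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks, welch
from scipy.signal.windows import hann

from .signal_io import AudioSegment, EmptyInputError
from .vmd_core import HilbertSpectrum


@dataclass
class SmoothedSpectrum:
    """A smoothed log-scale spectral profile on a uniform frequency grid."""

    values: np.ndarray  # log10 energy (vmd) or dB (fft)
    freqs_hz: np.ndarray
    source: str  # "vmd" | "fft"


@dataclass
class SpectralFeature:
    """A measured spectral peak or notch."""

    freq_khz: float
    prominence: float  # log10-energy units (vmd) or dB (fft)
    kind: str  # "peak" | "notch"
    scaled_prominence: Optional[float] = None  # set by the classifier


def _smooth(values: np.ndarray, med: int, avg: int) -> np.ndarray:
    """Median then moving-average filter, replicate-padded at the edges."""
    out = median_filter(values, size=med, mode="nearest")
    return uniform_filter1d(out, size=avg, mode="nearest")


def vmd_energy_spectrum(H: HilbertSpectrum, med: int = 17, avg: int = 11) -> SmoothedSpectrum:
    """Collapse a VMD-gram to a smoothed log10 energy-vs-frequency profile.

    Sums instantaneous energy over time in each frequency bin, converts
    to base-10 log (empty bins floored at 1e-12 of the maximum so the
    log stays finite), then smooths with a 17-point median filter and an
    11-point moving average.
    """
    sums = np.asarray(H.H.sum(axis=1)).ravel()
    peak = sums.max()
    if peak <= 0:
        raise EmptyInputError("empty Hilbert spectrum")
    logvals = np.log10(np.maximum(sums, 1e-12 * peak))
    return SmoothedSpectrum(values=_smooth(logvals, med, avg), freqs_hz=H.freqs_hz, source="vmd")


def welch_spectrum(
    x: AudioSegment,
    nfft: int = 2048,
    overlap: float = 0.5,
    med: int = 21,
    avg: int = 15,
) -> SmoothedSpectrum:
    """Smoothed Welch power spectrum in dB.

    2048-point Hann segments with 50% overlap give a 48.83 Hz bin
    spacing at 100 kHz sampling. Snippets shorter than one segment are
    zero-padded (sub-millisecond clicks are far shorter than 2048
    samples). Smoothing: 21-point median then 15-point moving average.
    """
    s = x.samples
    if len(s) < nfft:
        s = np.pad(s, (0, nfft - len(s)))
    freqs, psd = welch(
        s,
        fs=x.fs,
        window=hann(nfft, sym=False),
        nperseg=nfft,
        noverlap=int(round(overlap * nfft)),
        detrend=False,
    )
    peak = psd.max()
    if peak <= 0:
        raise EmptyInputError("all-zero snippet has no power spectrum")
    db = 10.0 * np.log10(np.maximum(psd, 1e-12 * peak))
    return SmoothedSpectrum(values=_smooth(db, med, avg), freqs_hz=freqs, source="fft")


def extract_features(
    spec: SmoothedSpectrum,
    prom_min: float,
    band_khz: Optional[tuple] = (10.0, 48.0),
) -> List[SpectralFeature]:
    """Locate peaks and notches with prominence above a threshold.

    Topographic prominence (height above the higher of the two bounding
    saddles) is computed on the profile for peaks and on its negation
    for notches, restricted to the search band (default 10-48 kHz: the
    detector's enhancement removes content below 10 kHz and all species
    template components lie within 17-41 kHz). Results are sorted by
    frequency.
    """
    values = spec.values
    freqs = spec.freqs_hz
    if band_khz is not None:
        sel = (freqs >= band_khz[0] * 1e3) & (freqs <= band_khz[1] * 1e3)
        values = values[sel]
        freqs = freqs[sel]
    out: List[SpectralFeature] = []
    for kind, sign in (("peak", 1.0), ("notch", -1.0)):
        idx, props = find_peaks(sign * values, prominence=prom_min)
        out.extend(
            SpectralFeature(freq_khz=freqs[i] / 1e3, prominence=float(p), kind=kind)
            for i, p in zip(idx, props["prominences"])
        )
    return sorted(out, key=lambda f: f.freq_khz)
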