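"""Ground-truthed synthetic recordings and scoring metrics.

The generator emulates the study conditions of duty-cycled passive
acoustic recorders: 4.5 s mono snippets at 100 kHz containing
sub-millisecond broadband pulses whose spectra carry a species-specific
peak/notch comb (Gaussian bumps and dips at the template frequencies on
a flat 10-48 kHz base), tonal "electrical" noise bands at multiples of
4.17 kHz, and a white Gaussian background at a configurable in-band
SNR. Ground truth (pulse bounds and species) is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal.windows import tukey

from .bayes_classifier import SpeciesTemplate, builtin_templates
from .signal_io import AudioSegment

#: feature band of the click spectral model, Hz
CLICK_BAND_HZ = (10_000.0, 48_000.0)


@dataclass
class SyntheticGroundTruth:
    """Exact event bounds and species of one synthetic file."""

    events: List[tuple]  # (start_s, end_s, species)
    snr_db: float
    electrical_band_spacing_hz: float
    seed: int


@dataclass
class MetricsReport:
    """Confusion counts with the derived percentages.

    ``accuracy`` is 100 x (sum of diagonal counts) / total;
    per-class precision and recall follow the standard
    confusion-matrix definitions. All percentages are rounded to two
    decimals.
    """

    confusion: Dict[Tuple[str, str], int]  # (truth, predicted) -> count
    precision: Dict[str, float]
    recall: Dict[str, float]
    accuracy: float


def _spectral_envelope(
    freqs_hz: np.ndarray,
    template: SpeciesTemplate,
    rng: Optional[np.random.Generator] = None,
    peak_gain: float = 4.0,
    notch_depth: float = 0.95,
    peak_width_frac: float = 0.5,
    notch_width_frac: float = 1.0,
    center_jitter_frac: float = 0.10,
    edge_hz: float = 1500.0,
) -> np.ndarray:
    """Target magnitude spectrum: banded base + template bumps and dips.

    Template SDs describe across-click scatter of peak positions, not
    within-click spectral width, so bump widths are a fraction of the SD
    (narrow, resolvable peaks) while each bump/dip center is jittered by
    ``center_jitter_frac`` SDs per click to emulate that scatter. Notch
    dips keep the full SD width so they survive the spectral smearing of
    a sub-millisecond pulse.
    """
    lo, hi = CLICK_BAND_HZ
    # raised-cosine transitions of width 2*edge_hz centered on the band edges
    lo_ramp = np.clip((freqs_hz - (lo - edge_hz)) / (2 * edge_hz), 0.0, 1.0)
    hi_ramp = np.clip(((hi + edge_hz) - freqs_hz) / (2 * edge_hz), 0.0, 1.0)
    shape = 0.25 * (1 - np.cos(np.pi * lo_ramp)) * (1 - np.cos(np.pi * hi_ramp))
    base = 1e-4 + (1 - 1e-4) * shape
    mag = base.copy()
    jit = (lambda: 0.0) if rng is None else (lambda: float(rng.standard_normal()))
    for c in template.peaks:
        mu = (c.mean_khz + center_jitter_frac * c.sd_khz * jit()) * 1e3
        width = peak_width_frac * c.sd_khz * 1e3
        mag += peak_gain * base * np.exp(-0.5 * ((freqs_hz - mu) / width) ** 2)
    for c in template.notches:
        mu = (c.mean_khz + center_jitter_frac * c.sd_khz * jit()) * 1e3
        width = notch_width_frac * c.sd_khz * 1e3
        mag *= 1.0 - notch_depth * np.exp(-0.5 * ((freqs_hz - mu) / width) ** 2)
    return mag


def synth_click(
    template: SpeciesTemplate,
    fs: float = 100_000.0,
    dur_ms: float = 1.0,
    seed: int = 0,
    phase_jitter: float = 0.25,
) -> np.ndarray:
    """Synthesize one broadband pulse carrying a species' peak/notch comb.

    A target magnitude spectrum (flat 10-48 kHz base, narrow Gaussian
    bumps near the template peak means, wider Gaussian dips near the
    notch means, with per-click position scatter drawn from the template
    SDs) is inverted to the time domain with seeded, mostly-coherent
    phase (small uniform jitter), producing a compact impulse-like click
    whose short-window spectrum is faithful to the target; a Tukey
    envelope restricts support to ``dur_ms`` and the pulse is normalized
    to unit peak amplitude.
    """
    if not 0.2 <= dur_ms <= 5.0:
        raise ValueError(f"click duration must be in [0.2, 5] ms, got {dur_ms}")
    f_max = max(c.mean_khz for c in template.peaks + template.notches) * 1e3
    if fs < 2 * f_max:
        raise ValueError(f"fs={fs} cannot represent template content up to {f_max} Hz")
    n = int(round(dur_ms * 1e-3 * fs))
    if n < 8:
        raise ValueError("click too short at this sampling rate")
    rng = np.random.default_rng(seed)
    nfft = 1 << max(12, int(np.ceil(np.log2(4 * n))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mag = _spectral_envelope(freqs, template, rng=rng)
    phase = phase_jitter * rng.uniform(-np.pi, np.pi, size=len(freqs))
    spectrum = mag * np.exp(1j * phase)
    x_long = np.fft.irfft(spectrum, n=nfft)
    x_long = np.roll(x_long, nfft // 2)  # center the impulse
    start = nfft // 2 - n // 2
    click = x_long[start : start + n] * tukey(n, alpha=0.5)
    return click / np.max(np.abs(click))


def _band_power(x: np.ndarray, fs: float, band: Tuple[float, float]) -> float:
    """Mean power of x restricted to a frequency band (Parseval)."""
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    # one-sided Parseval; interior bins count twice
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if len(x) % 2 == 0:
        w[-1] = 1.0
    return float(np.sum(w[sel] * np.abs(X[sel]) ** 2) / len(x) ** 2)


def synth_file(
    species: str = "Lo",
    n_clicks: int = 5,
    snr_db: float = 20.0,
    band_spacing_hz: float = 4170.0,
    duration_s: float = 4.5,
    fs: float = 100_000.0,
    seed: int = 0,
    dur_ms: float = 1.0,
    noise_sigma: float = 0.01,
    tone_level_db: float = -10.0,
    min_separation_s: float = 0.020,
) -> Tuple[AudioSegment, SyntheticGroundTruth]:
    """Build one ground-truthed synthetic recording.

    White Gaussian noise plus constant-amplitude "electrical" tonals at
    multiples of ``band_spacing_hz`` (default 4.17 kHz, at
    ``tone_level_db`` relative to the noise floor power), plus
    ``n_clicks`` pulses of one species at seeded random times separated
    by at least ``min_separation_s``. Each click is scaled so its SNR —
    10-48 kHz band power over the click duration versus the noise in
    the same band and duration — equals ``snr_db``.
    """
    if species not in ("Gg", "Lo"):
        raise ValueError(f"species must be 'Gg' or 'Lo', got {species!r}")
    if n_clicks < 0:
        raise ValueError("n_clicks must be nonnegative")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    noise = rng.normal(0.0, noise_sigma, size=n_samples)

    t = np.arange(n_samples) / fs
    tone_amp = noise_sigma * np.sqrt(2 * 10 ** (tone_level_db / 10))
    in_band_tone_power = 0.0
    k = 1
    while k * band_spacing_hz < fs / 2:
        f_tone = k * band_spacing_hz
        noise += tone_amp * np.sin(2 * np.pi * f_tone * t + rng.uniform(0, 2 * np.pi))
        if CLICK_BAND_HZ[0] <= f_tone <= CLICK_BAND_HZ[1]:
            in_band_tone_power += tone_amp**2 / 2
        k += 1

    gg, lo = builtin_templates()
    template = gg if species == "Gg" else lo
    n_click_samples = int(round(dur_ms * 1e-3 * fs))
    margin = 0.05
    span = duration_s - 2 * margin - dur_ms * 1e-3
    if n_clicks > 0 and span < (n_clicks - 1) * min_separation_s:
        raise ValueError(f"cannot place {n_clicks} clicks {min_separation_s}s apart in {duration_s}s")

    starts: List[float] = []
    for _ in range(10_000):
        if len(starts) == n_clicks:
            break
        cand = margin + rng.uniform(0, span)
        if all(abs(cand - s) >= min_separation_s + dur_ms * 1e-3 for s in starts):
            starts.append(cand)
    if len(starts) < n_clicks:
        raise ValueError("click placement failed; lower n_clicks or min_separation_s")
    starts.sort()

    # background in the click band: white-noise share plus tonal lines
    noise_band_power = (
        noise_sigma**2 * (CLICK_BAND_HZ[1] - CLICK_BAND_HZ[0]) / (fs / 2) + in_band_tone_power
    )
    events = []
    for start in starts:
        click = synth_click(template, fs=fs, dur_ms=dur_ms, seed=int(rng.integers(2**31)))
        p_click = _band_power(click, fs, CLICK_BAND_HZ)
        scale = np.sqrt(10 ** (snr_db / 10) * noise_band_power / p_click)
        i0 = int(round(start * fs))
        noise[i0 : i0 + n_click_samples] += scale * click
        events.append((start, start + n_click_samples / fs, species))

    truth = SyntheticGroundTruth(
        events=events, snr_db=snr_db, electrical_band_spacing_hz=band_spacing_hz, seed=seed
    )
    return AudioSegment(noise, fs), truth


def detection_rate(n_detected: int, n_total: int) -> float:
    """Detection accuracy as a percentage, rounded to two decimals."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    return round(100.0 * n_detected / n_total, 2)


def evaluate(truth_labels: Sequence[str], predicted_labels: Sequence[str]) -> MetricsReport:
    """Score predictions against truth with confusion-matrix metrics."""
    if len(truth_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(truth_labels)} vs {len(predicted_labels)}"
        )
    classes = sorted(set(truth_labels) | set(predicted_labels))
    confusion = {(a, b): 0 for a in classes for b in classes}
    for t, p in zip(truth_labels, predicted_labels):
        confusion[(t, p)] += 1
    precision, recall = {}, {}
    for c in classes:
        tp = confusion[(c, c)]
        pred_c = sum(confusion[(t, c)] for t in classes)
        true_c = sum(confusion[(c, p)] for p in classes)
        precision[c] = round(100.0 * tp / pred_c, 2) if pred_c else 0.0
        recall[c] = round(100.0 * tp / true_c, 2) if true_c else 0.0
    correct = sum(confusion[(c, c)] for c in classes)
    total = len(truth_labels)
    accuracy = round(100.0 * correct / total, 2) if total else 0.0
    return MetricsReport(confusion=confusion, precision=precision, recall=recall, accuracy=accuracy)
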