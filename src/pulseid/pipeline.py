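"""End-to-end composition: detect, extract features, classify.

Thin glue over the detector, the VMD-gram (or Welch) feature extractor
and the Bayesian classifier; this is what the command-line interface
and the synthetic benchmark drive.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

from .bayes_classifier import ClassificationResult, classify
from .detector import DetectionEvent, detect
from .signal_io import AudioSegment, EmptyInputError, RunConfig
from .spectral_features import extract_features, vmd_energy_spectrum, welch_spectrum
from .vmd_core import vmdgram

logger = logging.getLogger(__name__)

#: context kept around a detected event when slicing its snippet, seconds
SNIPPET_PAD_S = 0.003
#: snippets are capped at this length to bound VMD cost, seconds
SNIPPET_MAX_S = 0.5


def classify_segment(x: AudioSegment, cfg: Optional[RunConfig] = None) -> ClassificationResult:
    """Classify one detected snippet as Gg or Lo.

    Uses the configured feature extractor: ``vmd`` (VMD-gram energy
    spectrum, prominence threshold in log10-energy units) or ``fft``
    (Welch spectrum, threshold in dB).
    """
    cfg = cfg or RunConfig()
    if cfg.extractor == "vmd":
        spec = vmd_energy_spectrum(vmdgram(x, cfg))
        prom_min = cfg.vmd_prom_min
    else:
        spec = welch_spectrum(x)
        prom_min = cfg.fft_prom_min
    features = extract_features(spec, prom_min=prom_min, band_khz=cfg.feature_band_khz)
    return classify(features)


def classify_file(
    x: AudioSegment, cfg: Optional[RunConfig] = None
) -> Tuple[List[DetectionEvent], List[ClassificationResult], str]:
    """Detect and classify every event in a file; majority-vote a label.

    Returns (events, per-event results, file label). The file label is
    the majority over event labels, ties going to Gg; a file with no
    detections is labeled Gg by the same tie rule.
    """
    cfg = cfg or RunConfig()
    events = detect(x, cfg)
    results: List[ClassificationResult] = []
    for ev in events:
        start = max(x.t0, ev.start_s - SNIPPET_PAD_S)
        end = min(x.t0 + x.duration, max(ev.end_s + SNIPPET_PAD_S, start + 2 * SNIPPET_PAD_S))
        end = min(end, start + SNIPPET_MAX_S)
        try:
            snippet = x.slice(start, end)
            results.append(classify_segment(snippet, cfg))
        except EmptyInputError as exc:
            logger.warning("event at %.3f s skipped: %s", ev.start_s, exc)
            results.append(ClassificationResult(w_gg=0.0, w_lo=0.0, label="Gg"))
    n_lo = sum(1 for r in results if r.label == "Lo")
    n_gg = len(results) - n_lo
    return events, results, ("Lo" if n_lo > n_gg else "Gg")
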