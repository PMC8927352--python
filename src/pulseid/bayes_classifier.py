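"""Bayesian peak/notch weight classifier for Gg vs Lo pulsed signals.

Each species is described by a bank of Gaussian components — four
spectral peaks and three notches, each with a mean frequency, standard
deviation, and an occurrence prior (the fraction of that species'
pulsed signals in which the component appears, from published
Eastern-Tropical-Pacific click measurements). A measured feature y
matched to component theta contributes the weight

    w(theta | y) = N(y; mean, sd) * P(theta) * p

where N is the Gaussian density (in 1/kHz), P(theta) the occurrence
prior and p the feature's prominence scaled into (0, 1]. The species
with the larger summed weight wins; exact ties at three significant
digits go to Gg (the class on which precision is highest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spectral_features import SpectralFeature

logger = logging.getLogger(__name__)

Z95 = 1.96  # two-sided 95% Gaussian quantile


@dataclass(frozen=True)
class GaussianComponent:
    """One template peak or notch: a Gaussian over frequency (kHz)."""

    species: str  # "Gg" | "Lo"
    kind: str  # "peak" | "notch"
    index: int  # 1-based position within its kind
    mean_khz: float
    sd_khz: float
    occurrence: float  # prior probability in (0, 1]

    def __post_init__(self) -> None:
        if self.sd_khz < 0:
            raise ValueError("standard deviation must be nonnegative")
        if not 0 < self.occurrence <= 1:
            raise ValueError(f"occurrence prior must be in (0, 1], got {self.occurrence}")

    def density(self, freq_khz: float) -> float:
        """Gaussian density at a measured frequency, in 1/kHz."""
        z = (freq_khz - self.mean_khz) / self.sd_khz
        return math.exp(-0.5 * z * z) / (self.sd_khz * math.sqrt(2 * math.pi))


@dataclass(frozen=True)
class SpeciesTemplate:
    """A species' bank of four peak and three notch components."""

    species: str
    peaks: Tuple[GaussianComponent, ...]
    notches: Tuple[GaussianComponent, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) != 4 or len(self.notches) != 3:
            raise ValueError(
                f"{self.species}: expected 4 peaks and 3 notches, "
                f"got {len(self.peaks)} and {len(self.notches)}"
            )

    def components(self, kind: str) -> Tuple[GaussianComponent, ...]:
        return self.peaks if kind == "peak" else self.notches


@dataclass
class MatchedFeature:
    """A measured feature attached to one template component."""

    feature: SpectralFeature
    component: GaussianComponent
    weight: float = 0.0


@dataclass
class ClassificationResult:
    """Species decision with the per-species evidence."""

    w_gg: float
    w_lo: float
    label: str
    matches_gg: List[MatchedFeature] = field(default_factory=list)
    matches_lo: List[MatchedFeature] = field(default_factory=list)


def _bank(species: str, kind: str, rows: Sequence[tuple]) -> Tuple[GaussianComponent, ...]:
    return tuple(
        GaussianComponent(species, kind, i + 1, mean, sd, occ)
        for i, (mean, sd, occ) in enumerate(rows)
    )


# Published peak/notch statistics (mean kHz, SD kHz, occurrence fraction)
_GG = SpeciesTemplate(
    species="Gg",
    peaks=_bank("Gg", "peak", [(22.4, 0.8, 0.72), (25.5, 1.0, 0.45), (30.5, 1.1, 0.82), (38.8, 1.1, 0.48)]),
    notches=_bank("Gg", "notch", [(19.6, 1.3, 0.46), (27.7, 1.1, 0.64), (35.9, 1.2, 0.54)]),
)
_LO = SpeciesTemplate(
    species="Lo",
    peaks=_bank("Lo", "peak", [(22.2, 0.6, 0.89), (26.6, 0.9, 0.76), (33.7, 1.4, 0.45), (37.3, 1.4, 0.62)]),
    notches=_bank("Lo", "notch", [(19.0, 1.1, 0.51), (24.5, 0.9, 0.75), (29.7, 1.4, 0.66)]),
)


def builtin_templates() -> Tuple[SpeciesTemplate, SpeciesTemplate]:
    """The built-in (Gg, Lo) template banks."""
    return _GG, _LO


def load_templates(path: str | Path) -> Tuple[SpeciesTemplate, SpeciesTemplate]:
    """Load (Gg, Lo) templates from a CSV or YAML table.

    Columns/keys: species, kind, index, mean_khz, sd_khz, occurrence.
    Lets region-specific banks replace the built-in one (peak/notch
    patterns are not stereotyped across geography).
    """
    import pandas as pd
    import yaml

    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        rows = pd.DataFrame(yaml.safe_load(path.read_text()))
    else:
        rows = pd.read_csv(path)
    out = []
    for species in ("Gg", "Lo"):
        sub = rows[rows["species"] == species]
        comps = {
            kind: tuple(
                GaussianComponent(
                    species, kind, int(r["index"]), float(r["mean_khz"]),
                    float(r["sd_khz"]), float(r["occurrence"]),
                )
                for _, r in sub[sub["kind"] == kind].sort_values("index").iterrows()
            )
            for kind in ("peak", "notch")
        }
        out.append(SpeciesTemplate(species, comps["peak"], comps["notch"]))
    return out[0], out[1]


def confidence_interval(c: GaussianComponent) -> Tuple[float, float]:
    """95% confidence interval: mean +/- 1.96 SD, in kHz."""
    return (c.mean_khz - Z95 * c.sd_khz, c.mean_khz + Z95 * c.sd_khz)


def map_assign(freq_khz: float, candidates: Sequence[GaussianComponent]) -> GaussianComponent:
    """Resolve an ambiguous measurement by maximum a posteriori choice.

    Among components whose confidence intervals all contain the
    measured frequency, returns the one maximizing density * occurrence
    prior. Ties break toward the lower-mean component.
    """
    if not candidates:
        raise ValueError("map_assign needs at least one candidate component")
    ranked = sorted(candidates, key=lambda c: c.mean_khz)
    scores = [c.density(freq_khz) * c.occurrence for c in ranked]
    return ranked[int(np.argmax(scores))]


def match_features(
    features: Sequence[SpectralFeature], template: SpeciesTemplate
) -> List[MatchedFeature]:
    """Attach measured features to one species' template components.

    1. A feature outside every same-kind component's 95% CI is
       discarded; inside exactly one CI it attaches to that component;
       inside several it is resolved by :func:`map_assign`.
    2. If several features land on one component, the most prominent
       survives (ties toward lower frequency).
    3. Surviving peak prominences are scaled by their maximum, and
       notch prominences by theirs, so each group's strongest feature
       gets scaled prominence 1.0 and weaker evidence still counts.
    """
    per_component: Dict[GaussianComponent, SpectralFeature] = {}
    for feat in features:
        candidates = [
            c
            for c in template.components(feat.kind)
            if confidence_interval(c)[0] < feat.freq_khz < confidence_interval(c)[1]
        ]
        if not candidates:
            logger.debug(
                "%s %.2f kHz outside all %s CIs; discarded", feat.kind, feat.freq_khz,
                template.species,
            )
            continue
        comp = candidates[0] if len(candidates) == 1 else map_assign(feat.freq_khz, candidates)
        held = per_component.get(comp)
        if held is None or (feat.prominence, -feat.freq_khz) > (held.prominence, -held.freq_khz):
            per_component[comp] = feat
    matches = []
    for kind in ("peak", "notch"):
        group = [(c, f) for c, f in per_component.items() if c.kind == kind]
        if not group:
            continue
        top = max(f.prominence for _, f in group)
        for comp, feat in group:
            scaled = feat.prominence / top if top > 0 else 0.0
            matches.append(
                MatchedFeature(feature=replace(feat, scaled_prominence=scaled), component=comp)
            )
    for m in matches:
        m.weight = feature_weight(m)
    return sorted(matches, key=lambda m: (m.component.kind, m.component.index))


def feature_weight(m: MatchedFeature) -> float:
    """Weight of one match: density (1/kHz) x occurrence x scaled prominence."""
    p = m.feature.scaled_prominence
    if p is None:
        raise ValueError("scaled prominence must be set before weighting")
    return m.component.density(m.feature.freq_khz) * m.component.occurrence * p


def _sig3(x: float) -> float:
    return float(f"{x:.3g}")


def classify(
    features: Sequence[SpectralFeature],
    templates: Optional[Tuple[SpeciesTemplate, SpeciesTemplate]] = None,
) -> ClassificationResult:
    """Decide the species of one snippet from its measured features.

    Features are matched independently against both species' banks (a
    measurement may legitimately support both), weights are summed per
    species, and the totals are compared after rounding to three
    significant digits; Lo wins strictly larger, anything else
    (including no evidence at all) is labeled Gg.
    """
    gg, lo = templates if templates is not None else builtin_templates()
    matches_gg = match_features(features, gg)
    matches_lo = match_features(features, lo)
    w_gg = sum(m.weight for m in matches_gg)
    w_lo = sum(m.weight for m in matches_lo)
    label = "Lo" if _sig3(w_lo) > _sig3(w_gg) else "Gg"
    return ClassificationResult(
        w_gg=w_gg, w_lo=w_lo, label=label, matches_gg=matches_gg, matches_lo=matches_lo
    )
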