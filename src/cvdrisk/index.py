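"""Banded risk-score index: OR -> score conversion, AROP, RCI, R and risk levels.

The index follows the Harvard risk-index scheme: each factor's relative
risk is banded into an integer score (harmful bands positive, protective
bands negative), the population-average score AROP is the exposure-weighted
sum of the factor scores, an individual's score RCI is the sum of the
scores of the factors they carry, and the individual-to-population risk
ratio is R = RCI / AROP, classified into seven ordered levels.

The printed band bounds are one-decimal renderings of contiguous ranges;
bands are therefore implemented as contiguous half-open intervals
``[lo, hi)`` partitioning (0, inf).
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass

from .cohort import MODEL_FACTORS, RiskFactorProfile

__all__ = [
    "ScoreBand",
    "ScoreBandTable",
    "DEFAULT_BANDS",
    "ExposureRegistry",
    "DEFAULT_EXPOSURES",
    "MODELING_GROUP_ORS",
    "RiskScoreModel",
    "RiskLevel",
    "RiskAssessment",
    "score_from_or",
    "build_score_model",
    "default_score_model",
    "compute_rci",
    "compute_r",
    "classify_risk_level",
    "assess_profile",
    "achievable_r_grid",
]


@dataclass(frozen=True)
class ScoreBand:
    """Half-open OR interval ``[lo, hi)`` mapping to a signed integer score."""

    lo: float
    hi: float
    score: int

    def __contains__(self, or_: float) -> bool:
        return self.lo <= or_ < self.hi


@dataclass(frozen=True)
class ScoreBandTable:
    """Ordered bands partitioning (0, inf); score 0 exactly on the null band."""

    bands: tuple[ScoreBand, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.lo)
        if ordered[0].lo != 0.0 or ordered[-1].hi != math.inf:
            raise ValueError("bands must cover (0, inf)")
        for a, b in itertools.pairwise(ordered):
            if a.hi != b.lo:
                raise ValueError(f"bands must be contiguous; gap at {a.hi}..{b.lo}")
        if sum(1 for b in self.bands if b.score == 0) != 1:
            raise ValueError("exactly one null band (score 0) required")

    def lookup(self, or_: float) -> int:
        if not or_ > 0 or math.isnan(or_):
            raise ValueError(f"OR must be strictly positive, got {or_}")
        for band in self.bands:
            if or_ in band:
                return band.score
        return next(b.score for b in self.bands if b.hi == math.inf)  # or_ == inf


#: Score magnitudes 0/5/10/25/50; protective bands mirror harmful ones with
#: negative sign.
DEFAULT_BANDS = ScoreBandTable(
    bands=(
        ScoreBand(0.0, 0.2, -50),
        ScoreBand(0.2, 0.4, -25),
        ScoreBand(0.4, 0.7, -10),
        ScoreBand(0.7, 0.9, -5),
        ScoreBand(0.9, 1.1, 0),
        ScoreBand(1.1, 1.5, 5),
        ScoreBand(1.5, 3.0, 10),
        ScoreBand(3.0, 7.0, 25),
        ScoreBand(7.0, math.inf, 50),
    )
)


@dataclass(frozen=True)
class ExposureRegistry:
    """Reference-population exposure rate per factor, with a source citation."""

    rates: dict[str, float]
    sources: dict[str, str]

    def __post_init__(self) -> None:
        # 0 is tolerated (a factor nobody in the reference population carries)
        # so that degenerate AROP = 0 models are constructible and refused at
        # the compute_r stage rather than here.
        for name, er in self.rates.items():
            if not 0.0 <= er <= 1.0:
                raise ValueError(f"exposure rate for {name} must be in [0,1], got {er}")

    def rate(self, factor: str) -> float:
        try:
            return self.rates[factor]
        except KeyError:
            raise KeyError(f"no exposure rate registered for factor {factor!r}") from None


#: Shipped reference exposure rates.  Note: the exercise entry is the rate
#: of *regular* exercise in the source population even though the scored
#: factor is lack of exercise; it is kept as published because the published
#: population-average score (22.20) is only reproducible with it.
DEFAULT_EXPOSURES = ExposureRegistry(
    rates={
        "age_ge_60": 0.17,
        "lack_of_exercise": 0.82,
        "hypertension": 0.28,
        "diabetes": 0.11,
        "smoking": 0.28,
        "family_history_cvd": 0.14,
    },
    sources={
        "age_ge_60": "China health statistics yearbook 2019",
        "lack_of_exercise": "study sample (regular-exercise proportion)",
        "hypertension": "Chinese hypertension prevention/treatment guidelines (2018 rev.)",
        "diabetes": "Chinese type-2 diabetes prevention/treatment guidelines (2017)",
        "smoking": "Chinese stroke prevention/treatment report 2017",
        "family_history_cvd": "study sample",
    },
)

#: Modeling-half adjusted ORs used to build the shipped score model.
MODELING_GROUP_ORS: dict[str, float] = {
    "age_ge_60": 3.171,
    "lack_of_exercise": 2.306,
    "hypertension": 2.436,
    "diabetes": 3.220,
    "smoking": 1.877,
    "family_history_cvd": 2.315,
}


@dataclass(frozen=True)
class RiskScoreModel:
    """Factor -> score map with its exposure registry and derived AROP."""

    scores: dict[str, int]
    registry: ExposureRegistry
    arop: float
    provenance: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "scores": self.scores,
                "exposure_rates": self.registry.rates,
                "exposure_sources": self.registry.sources,
                "arop": self.arop,
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskScoreModel":
        d = json.loads(text)
        registry = ExposureRegistry(
            rates=d["exposure_rates"], sources=d.get("exposure_sources", {})
        )
        return build_score_model_from_scores(
            d["scores"], registry, provenance=d.get("provenance", "")
        )


class RiskLevel(enum.IntEnum):
    """Seven ordered risk levels; comparison follows increasing risk."""

    VERY_LOW = 0
    LOWER = 1
    LOW = 2
    MODERATE = 3
    HIGH = 4
    HIGHER = 5
    VERY_HIGH = 6

    @property
    def label(self) -> str:
        return _LEVEL_LABELS[self]


_LEVEL_LABELS = {
    RiskLevel.VERY_LOW: "Very low",
    RiskLevel.LOWER: "Lower",
    RiskLevel.LOW: "Low",
    RiskLevel.MODERATE: "Moderate",
    RiskLevel.HIGH: "High",
    RiskLevel.HIGHER: "Higher",
    RiskLevel.VERY_HIGH: "Very high",
}


@dataclass(frozen=True)
class RiskAssessment:
    id: int
    rci: float
    r: float
    level: RiskLevel


def score_from_or(or_: float, bands: ScoreBandTable = DEFAULT_BANDS) -> int:
    """Banded signed score for an OR; harmful bands positive, protective negative."""
    return bands.lookup(or_)


def build_score_model(
    or_map: dict[str, float],
    registry: ExposureRegistry = DEFAULT_EXPOSURES,
    bands: ScoreBandTable = DEFAULT_BANDS,
    provenance: str = "",
) -> RiskScoreModel:
    """Convert per-factor ORs to scores and derive AROP = sum(ER_f * RC_f)."""
    scores = {f: score_from_or(or_, bands) for f, or_ in or_map.items()}
    return build_score_model_from_scores(scores, registry, provenance)


def build_score_model_from_scores(
    scores: dict[str, int],
    registry: ExposureRegistry = DEFAULT_EXPOSURES,
    provenance: str = "",
) -> RiskScoreModel:
    missing = [f for f in scores if f not in registry.rates]
    if missing:
        raise KeyError(f"no exposure rate registered for factor(s): {', '.join(missing)}")
    arop = sum(registry.rates[f] * scores[f] for f in scores)
    return RiskScoreModel(
        scores=dict(scores), registry=registry, arop=arop, provenance=provenance
    )


def default_score_model() -> RiskScoreModel:
    """The shipped score model built from the published modeling-group ORs."""
    return build_score_model(
        MODELING_GROUP_ORS, DEFAULT_EXPOSURES, DEFAULT_BANDS, provenance="modeling-group"
    )


def compute_rci(profile: RiskFactorProfile, model: RiskScoreModel) -> float:
    """Sum of factor scores over the factors present in the profile."""
    return float(sum(model.scores[f] for f in model.scores if getattr(profile, f)))


def compute_r(rci: float, model: RiskScoreModel) -> float:
    """Individual-to-population risk ratio R = RCI / AROP (unrounded)."""
    if not model.arop > 0:
        raise ValueError(f"AROP must be positive to compute R, got {model.arop}")
    return rci / model.arop


def classify_risk_level(r: float) -> RiskLevel:
    """Total, monotone classification of R into the seven levels.

    Intervals are lower-closed so every real R (including 0, which the
    all-positive score models produce for factor-free individuals) gets a
    level: very_low r <= 0; lower (0, 0.5); low [0.5, 0.9);
    moderate [0.9, 1.1); high [1.1, 2.0); higher [2.0, 5.0);
    very_high r >= 5.0.
    """
    if math.isnan(r):
        raise ValueError("R is NaN")
    if r <= 0.0:
        return RiskLevel.VERY_LOW
    if r < 0.5:
        return RiskLevel.LOWER
    if r < 0.9:
        return RiskLevel.LOW
    if r < 1.1:
        return RiskLevel.MODERATE
    if r < 2.0:
        return RiskLevel.HIGH
    if r < 5.0:
        return RiskLevel.HIGHER
    return RiskLevel.VERY_HIGH


def assess_profile(profile: RiskFactorProfile, model: RiskScoreModel) -> RiskAssessment:
    rci = compute_rci(profile, model)
    r = compute_r(rci, model)
    return RiskAssessment(id=profile.id, rci=rci, r=r, level=classify_risk_level(r))


def achievable_r_grid(model: RiskScoreModel, ndigits: int = 2) -> list[float]:
    """All positive R values achievable under the model, by subset-sum
    enumeration over the factor scores, rounded to ``ndigits`` and sorted."""
    values = {0.0}
    sums = {0}
    for score in model.scores.values():
        sums |= {s + score for s in sums}
    for s in sums:
        values.add(round(s / model.arop, ndigits))
    return sorted(v for v in values if v > 0)


# keep canonical factor order available alongside the model surface
FACTOR_ORDER = MODEL_FACTORS
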