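"""Per-variant pathogenicity classification under prenatal reporting rules.

Classes, in strict precedence order:

1. ``known_pathogenic`` — exact-coordinate hit in the known-pathogenic
   mutation table (reporting category (a): previously reported in the
   literature and/or mutation databases). Unconditional.
2. ``obligatory_pathogenic`` — damaging by mechanism (category (b)):
   nonsense, frameshift, canonical ±2 splice-site; in-frame indels only when
   the ``inframe_indels_obligatory`` flag is set (off by default — over-calling
   is the costlier error prenatally).
3. ``probable_pathogenic`` — composite in-silico score (the EMA score, the
   arithmetic mean of the available normalized predictor scores, on a 0-100
   scale) at or above the threshold (default 70), or a predicted splice
   disruption at an exon-boundary base.
4. ``vous`` — a missense/splice-region/other variant with absent or
   sub-threshold evidence.
5. ``likely_benign`` — synonymous without any splice prediction.

Classification is a pure function of (annotation, known-db hit, score,
config); identical inputs always give the identical class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

from .variant_model import AnnotatedVariant, Consequence


class VariantClass(IntEnum):
    """Ordered so that higher value = stronger pathogenicity evidence."""

    likely_benign = 0
    vous = 1
    probable_pathogenic = 2
    obligatory_pathogenic = 3
    known_pathogenic = 4

    @property
    def label(self) -> str:
        return self.name


OBLIGATORY_CONSEQUENCES = frozenset(
    {Consequence.nonsense, Consequence.frameshift, Consequence.canonical_splice}
)


@dataclass
class ClassifierConfig:
    score_threshold_probable: float = 70.0
    inframe_indels_obligatory: bool = False


@dataclass
class VariantAssessment:
    variant: AnnotatedVariant
    variant_class: VariantClass
    ema_score: Optional[float] = None
    rationale: list[str] = field(default_factory=list)

    @property
    def gene(self) -> str:
        return self.variant.gene


def ema_score(predictor_scores: dict[str, float]) -> Optional[float]:
    """Composite pathogenicity score: 100 x mean of available predictors.

    Missing predictors are excluded from the mean; with no predictors at all
    the score is absent (``None``), not zero.
    """
    if not predictor_scores:
        return None
    vals = list(predictor_scores.values())
    return 100.0 * sum(vals) / len(vals)


def _splice_at_exon_boundary(v: AnnotatedVariant) -> bool:
    d = v.annotation.distance_to_exon_boundary
    return v.annotation.splice_effect_predicted and d == 0


def classify_variant(
    v: AnnotatedVariant, config: ClassifierConfig | None = None
) -> VariantAssessment:
    """Assign exactly one pathogenicity class with an audit trail.

    Precondition: ``v`` survived frequency filtering (known-pathogenic
    variants are exempt there, so a common documented allele still arrives
    here and classifies as known_pathogenic).
    """
    cfg = config or ClassifierConfig()
    score = ema_score(v.annotation.predictor_scores)
    rationale: list[str] = []
    cons = v.annotation.consequence

    if v.known_pathogenic:
        rationale.append(f"known-pathogenic database hit ({v.known_citation or 'uncited'})")
        return VariantAssessment(v, VariantClass.known_pathogenic, score, rationale)

    if cons in OBLIGATORY_CONSEQUENCES or (
        cons == Consequence.inframe_indel and cfg.inframe_indels_obligatory
    ):
        rationale.append(f"obligatory-pathogenic consequence: {cons.value}")
        return VariantAssessment(v, VariantClass.obligatory_pathogenic, score, rationale)

    if score is not None and score >= cfg.score_threshold_probable:
        rationale.append(
            f"EMA score {score:g} >= threshold {cfg.score_threshold_probable:g}"
        )
        return VariantAssessment(v, VariantClass.probable_pathogenic, score, rationale)
    if _splice_at_exon_boundary(v):
        rationale.append("predicted splice disruption at exon-boundary base")
        return VariantAssessment(v, VariantClass.probable_pathogenic, score, rationale)

    if cons == Consequence.synonymous:
        if v.annotation.splice_effect_predicted:
            rationale.append("synonymous with predicted splice effect: uncertain")
            return VariantAssessment(v, VariantClass.vous, score, rationale)
        rationale.append("synonymous, no splice prediction")
        return VariantAssessment(v, VariantClass.likely_benign, score, rationale)

    if score is None:
        rationale.append(f"{cons.value} with no predictor scores: uncertain")
    else:
        rationale.append(
            f"{cons.value} with EMA score {score:g} below threshold "
            f"{cfg.score_threshold_probable:g}: uncertain"
        )
    return VariantAssessment(v, VariantClass.vous, score, rationale)
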