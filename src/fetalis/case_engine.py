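"""Case-level diagnosis: inheritance models, segregation, and reporting tier.

Combines classified variants with the gene's inheritance mode, proband
zygosity and optional parental genotypes into one of four tiers:

* ``definitive`` — diagnosis with segregation support: an autosomal-recessive
  genotype confirmed in trans (or homozygous), a confirmed de novo dominant
  mutation, or a dominant variant shown to segregate in an affected relative.
* ``highly_likely`` — a known or obligatory pathogenic dominant variant (or an
  unphased recessive pair anchored by one) without segregation confirmation.
* ``vous`` — no diagnosis, but at least one uncertain-to-probable candidate in
  a phenotype-matched gene remains for review.
* ``negative`` — nothing survives: no diagnoses and no candidates.

Recessive logic: a gene qualifies when the proband carries a homozygous
qualifying allele or a compound-heterozygous pair in which every allele is at
least probable_pathogenic AND either (i) one allele is known/obligatory
pathogenic or (ii) trans phase is confirmed by parental genotypes. Two
unphased in-silico-probable alleles alone remain review candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .classifier import ClassifierConfig, VariantAssessment, VariantClass, classify_variant
from .frequency_filter import FrequencyPolicy, apply_frequency_filter
from .panel_registry import GenePanel, Inheritance, VariantKey, lookup_gene
from .phenotype_prioritizer import (
    FindingSet,
    ICMap,
    Ontology,
    prioritize_genes,
)
from .variant_model import AnnotatedVariant, Zygosity

log = logging.getLogger("fetalis.case")


class Tier(str, Enum):
    definitive = "definitive"
    highly_likely = "highly_likely"
    vous = "vous"
    negative = "negative"


_TIER_RANK = {Tier.definitive: 3, Tier.highly_likely: 2, Tier.vous: 1, Tier.negative: 0}


class PhaseCall(str, Enum):
    confirmed_trans = "confirmed_trans"
    possible_unphased = "possible_unphased"
    cis_or_artifact = "cis_or_artifact"
    none = "none"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


@dataclass(frozen=True)
class ParentalGenotype:
    """Carrier status of each parent for one proband variant.

    ``None`` means that parent was unavailable for testing.
    """

    maternal: Optional[bool]
    paternal: Optional[bool]


@dataclass
class CaseInput:
    case_id: str
    findings: FindingSet
    variants: list[AnnotatedVariant]
    parental_genotypes: dict[VariantKey, ParentalGenotype] = field(default_factory=dict)
    fetal_sex: Sex = Sex.unknown
    family_history_flag: bool = False
    #: variant keys whose segregation with disease was confirmed in an
    #: affected relative (Sanger follow-up evidence, supplied per case)
    segregation_confirmed: frozenset[VariantKey] = frozenset()
    #: declared parental origin ("maternal"/"paternal") when reported upstream
    declared_inheritance: dict[VariantKey, str] = field(default_factory=dict)
    notes: dict[str, object] = field(default_factory=dict)


@dataclass
class Diagnosis:
    gene: str
    disorder: str
    inheritance_model: Inheritance
    assessments: list[VariantAssessment]
    segregation: str  # de_novo | confirmed_trans | homozygous | affected_relative | unconfirmed
    tier: Tier


@dataclass
class CaseResult:
    case_id: str
    tier: Tier
    diagnoses: list[Diagnosis]
    candidates_for_review: list[VariantAssessment]
    filter_trace: dict[str, int]
    gene_scores: dict[str, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class CaseConfig:
    frequency: FrequencyPolicy = field(default_factory=FrequencyPolicy)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    min_gene_score: float = 0.0
    #: demote a probable_pathogenic dominant candidate inherited from an
    #: apparently unaffected parent to VOUS (reduced confidence in dominant
    #: causality when the transmitting parent is unaffected)
    inherited_dominant_downgrade: bool = True


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------


def detect_compound_het(
    assessments: list[VariantAssessment],
    parental_genotypes: dict[VariantKey, ParentalGenotype],
) -> PhaseCall:
    """Phase a putative compound-heterozygous pair from parental genotypes.

    With >= 2 qualifying het variants: one maternal-only plus one
    paternal-only allele confirms trans; all alleles traced to the same
    single parent indicates cis (or an artifact); otherwise the pair is
    possible but unphased.
    """
    hets = assessments  # zygosity/class filtering is the caller's job
    if len(hets) < 2:
        return PhaseCall.none
    origins: list[Optional[str]] = []
    for a in hets:
        pg = parental_genotypes.get(a.variant.key)
        if pg is None or pg.maternal is None or pg.paternal is None:
            origins.append(None)
        elif pg.maternal and not pg.paternal:
            origins.append("maternal")
        elif pg.paternal and not pg.maternal:
            origins.append("paternal")
        elif not pg.maternal and not pg.paternal:
            origins.append("de_novo")
        else:
            origins.append("both")
    known = [o for o in origins if o in ("maternal", "paternal")]
    if "maternal" in known and "paternal" in known:
        return PhaseCall.confirmed_trans
    if len(known) == len(origins) and len(set(known)) == 1:
        return PhaseCall.cis_or_artifact
    return PhaseCall.possible_unphased


def _segregation_of(
    key: VariantKey,
    case: CaseInput,
) -> tuple[str, Optional[str]]:
    """Per-variant segregation status and an optional warning string."""
    pg = case.parental_genotypes.get(key)
    declared = case.declared_inheritance.get(key)
    if pg is not None and pg.maternal is False and pg.paternal is False:
        if declared in ("maternal", "paternal"):
            return "de_novo", (
                f"variant {key} declared {declared}ly inherited but absent from both "
                "parents; treating as de novo (segregation inconsistency)"
            )
        return "de_novo", None
    if pg is not None and pg.maternal:
        return "inherited_maternal", None
    if pg is not None and pg.paternal:
        return "inherited_paternal", None
    return "unknown", None


# ---------------------------------------------------------------------------
# Per-gene inheritance-model evaluation
# ---------------------------------------------------------------------------


def _proband_zygosity(a: VariantAssessment, proband_key: str = "PROBAND") -> Zygosity:
    gts = a.variant.variant.genotypes
    if proband_key in gts:
        return gts[proband_key]
    # single-sample fixtures may use any sample name; fall back to the first
    return next(iter(gts.values()), Zygosity.missing)


def _evaluate_dominant(
    gene_assessments: list[VariantAssessment],
    case: CaseInput,
    disorder: str,
    inheritance_model: Inheritance,
) -> tuple[Optional[Diagnosis], list[str]]:
    warnings: list[str] = []
    qualifying = [
        a
        for a in gene_assessments
        if a.variant_class in (VariantClass.known_pathogenic, VariantClass.obligatory_pathogenic)
    ]
    if not qualifying:
        return None, warnings
    best = max(qualifying, key=lambda a: a.variant_class)
    seg, warn = _segregation_of(best.variant.key, case)
    if warn:
        warnings.append(warn)
    if seg == "de_novo":
        tier, seg_label = Tier.definitive, "de_novo"
    elif best.variant.key in case.segregation_confirmed:
        tier, seg_label = Tier.definitive, "affected_relative"
    else:
        tier, seg_label = Tier.highly_likely, "unconfirmed"
    return (
        Diagnosis(best.gene, disorder, inheritance_model, [best], seg_label, tier),
        warnings,
    )


def _evaluate_recessive(
    gene_assessments: list[VariantAssessment],
    case: CaseInput,
    disorder: str,
    inheritance_model: Inheritance,
) -> tuple[Optional[Diagnosis], list[str]]:
    warnings: list[str] = []
    qualifying = [
        a for a in gene_assessments if a.variant_class >= VariantClass.probable_pathogenic
    ]
    strong = [
        a
        for a in qualifying
        if a.variant_class in (VariantClass.known_pathogenic, VariantClass.obligatory_pathogenic)
    ]
    homs = [a for a in qualifying if _proband_zygosity(a) == Zygosity.hom_alt]
    for a in homs:
        pg = case.parental_genotypes.get(a.variant.key)
        both_carriers = pg is not None and bool(pg.maternal) and bool(pg.paternal)
        if a in strong or both_carriers:
            return (
                Diagnosis(a.gene, disorder, inheritance_model, [a], "homozygous", Tier.definitive),
                warnings,
            )
    hets = [a for a in qualifying if _proband_zygosity(a) == Zygosity.het]
    if len(hets) >= 2:
        phase = detect_compound_het(hets, case.parental_genotypes)
        pair = sorted(hets, key=lambda a: (-a.variant_class, a.variant.key))[:2]
        if phase == PhaseCall.confirmed_trans:
            return (
                Diagnosis(
                    pair[0].gene, disorder, inheritance_model, pair, "confirmed_trans", Tier.definitive
                ),
                warnings,
            )
        if phase == PhaseCall.possible_unphased and strong:
            return (
                Diagnosis(
                    pair[0].gene, disorder, inheritance_model, pair, "unconfirmed", Tier.highly_likely
                ),
                warnings,
            )
        if phase == PhaseCall.cis_or_artifact:
            warnings.append(
                f"gene {pair[0].gene}: two qualifying variants phased to the same parent "
                "(cis or artifact); not a recessive diagnosis"
            )
    return None, warnings


def _evaluate_x_linked(
    gene_assessments: list[VariantAssessment],
    case: CaseInput,
    disorder: str,
) -> tuple[Optional[Diagnosis], list[str]]:
    if case.fetal_sex == Sex.male:
        hemi = [
            a
            for a in gene_assessments
            if _proband_zygosity(a) == Zygosity.hom_alt
            and a.variant_class
            in (VariantClass.known_pathogenic, VariantClass.obligatory_pathogenic)
        ]
        if hemi:
            best = max(hemi, key=lambda a: a.variant_class)
            seg, warn = _segregation_of(best.variant.key, case)
            tier = Tier.definitive if seg == "de_novo" else Tier.highly_likely
            seg_label = "de_novo" if seg == "de_novo" else "unconfirmed"
            return (
                Diagnosis(best.gene, disorder, Inheritance.XL, [best], seg_label, tier),
                [warn] if warn else [],
            )
        return None, []
    # female or unknown sex: biallelic requirement, as for autosomal recessive
    return _evaluate_recessive(gene_assessments, case, disorder, Inheritance.XL)


# ---------------------------------------------------------------------------
# Case evaluation
# ---------------------------------------------------------------------------


def evaluate_case(
    case: CaseInput,
    panel: GenePanel,
    ontology: Ontology,
    icmap: ICMap,
    config: CaseConfig | None = None,
    filter_trace: Optional[dict[str, int]] = None,
) -> CaseResult:
    """Run phenotype gating, frequency filtering, classification and tiering.

    ``case.variants`` is the panel-restricted annotated variant set; the
    stages here append to any upstream ``filter_trace`` counts.
    """
    cfg = config or CaseConfig()
    trace: dict[str, int] = dict(filter_trace or {})
    trace.setdefault("panel_restricted", len(case.variants))
    warnings: list[str] = []

    priority = prioritize_genes(panel, case.findings, icmap, ontology, cfg.min_gene_score)
    gated = [v for v in case.variants if v.gene in priority.prioritized_set]
    trace["phenotype_prioritized"] = len(gated)
    if not priority.prioritized_set:
        warnings.append(
            "no panel gene matches the reported findings; result is negative by construction"
        )

    survivors, freq_audit = apply_frequency_filter(gated, cfg.frequency, panel.inheritance_map())
    trace["after_local_frequency"] = len(gated) - freq_audit.stage_discards["local"]
    trace["after_international_frequency"] = len(survivors)

    assessments = [classify_variant(v, cfg.classifier) for v in survivors]
    significant = [a for a in assessments if a.variant_class >= VariantClass.vous]
    trace["classified_significant"] = len(significant)

    # dominant candidates inherited from an apparently unaffected parent:
    # optionally demote in-silico-only (probable) calls to VOUS. Restricted
    # to strictly dominant genes — for dual-mode (AD_AR) genes the recessive
    # model must still see inherited probable alleles as carrier alleles.
    if cfg.inherited_dominant_downgrade:
        for a in significant:
            entry = lookup_gene(panel, a.gene)
            if entry is None or entry.inheritance != Inheritance.AD:
                continue
            seg, _ = _segregation_of(a.variant.key, case)
            if (
                a.variant_class == VariantClass.probable_pathogenic
                and seg in ("inherited_maternal", "inherited_paternal")
                and _proband_zygosity(a) == Zygosity.het
            ):
                a.variant_class = VariantClass.vous
                a.rationale.append(
                    f"dominant candidate {seg.replace('inherited_', '')}ly inherited from an "
                    "apparently unaffected parent: downgraded to VOUS"
                )

    by_gene: dict[str, list[VariantAssessment]] = {}
    for a in significant:
        by_gene.setdefault(a.gene, []).append(a)

    diagnoses: list[Diagnosis] = []
    for gene, gas in sorted(by_gene.items()):
        entry = lookup_gene(panel, gene)
        if entry is None:  # unreachable when inputs were panel-restricted
            continue
        models: list[tuple[Optional[Diagnosis], list[str]]] = []
        if entry.inheritance == Inheritance.AD:
            models.append(_evaluate_dominant(gas, case, entry.disorder, Inheritance.AD))
        elif entry.inheritance == Inheritance.AR:
            models.append(_evaluate_recessive(gas, case, entry.disorder, Inheritance.AR))
        elif entry.inheritance == Inheritance.XL:
            models.append(_evaluate_x_linked(gas, case, entry.disorder))
        else:  # AD_AR: try both, report every qualifying model (best tier first)
            models.append(_evaluate_recessive(gas, case, entry.disorder, Inheritance.AD_AR))
            models.append(_evaluate_dominant(gas, case, entry.disorder, Inheritance.AD_AR))
        for diag, warns in models:
            warnings.extend(warns)
            if diag is not None:
                diagnoses.append(diag)

    diagnoses.sort(key=lambda d: (-_TIER_RANK[d.tier], d.gene))

    candidates = sorted(
        significant,
        key=lambda a: (
            -a.variant_class,
            -priority.score_of(a.gene),
            -(a.ema_score if a.ema_score is not None else -1.0),
            a.gene,
            a.variant.key,
        ),
    )
    trace["candidates_for_review"] = len(candidates)

    if diagnoses:
        tier = diagnoses[0].tier
    elif candidates:
        tier = Tier.vous
    else:
        tier = Tier.negative

    gene_scores = {g: priority.score_of(g) for g in by_gene}
    log.info("case %s: tier %s, %d diagnoses, %d candidates",
             case.case_id, tier.value, len(diagnoses), len(candidates))
    return CaseResult(
        case_id=case.case_id,
        tier=tier,
        diagnoses=diagnoses,
        candidates_for_review=candidates,
        filter_trace=trace,
        gene_scores=gene_scores,
        warnings=warnings,
    )
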