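"""Compound-het phasing, inheritance models and case-level tiering."""

import copy

import pytest

from fetalis.case_engine import (
    CaseConfig,
    ParentalGenotype,
    PhaseCall,
    Tier,
    detect_compound_het,
    evaluate_case,
)
from fetalis.classifier import VariantAssessment, VariantClass
from fetalis.fixtures import EXPECTED_TABLE1_TIERS, table1_cohort
from fetalis.variant_model import (
    AnnotatedVariant,
    Consequence,
    Variant,
    VariantAnnotation,
    Zygosity,
)

# --- compound-het phasing ---------------------------------------------------


def _assessment(pos, klass=VariantClass.probable_pathogenic):
    av = AnnotatedVariant(
        Variant("2", pos, "A", "G", {"PROBAND": Zygosity.het}),
        VariantAnnotation("NEB", Consequence.missense),
    )
    return VariantAssessment(av, klass, 80.0, ["x"])


def test_trans_pair_confirmed_by_opposite_parental_origin():
    a, b = _assessment(100), _assessment(200)
    parental = {
        a.variant.key: ParentalGenotype(True, False),
        b.variant.key: ParentalGenotype(False, True),
    }
    assert detect_compound_het([a, b], parental) == PhaseCall.confirmed_trans


def test_pair_without_parental_data_is_possible_unphased():
    a, b = _assessment(100), _assessment(200)
    assert detect_compound_het([a, b], {}) == PhaseCall.possible_unphased


def test_pair_from_same_parent_is_cis_or_artifact():
    a, b = _assessment(100), _assessment(200)
    parental = {
        a.variant.key: ParentalGenotype(True, False),
        b.variant.key: ParentalGenotype(True, False),
    }
    assert detect_compound_het([a, b], parental) == PhaseCall.cis_or_artifact


def test_fewer_than_two_variants_is_none():
    assert detect_compound_het([_assessment(100)], {}) == PhaseCall.none


def test_partial_parental_data_stays_unphased():
    a, b = _assessment(100), _assessment(200)
    parental = {a.variant.key: ParentalGenotype(True, False)}
    assert detect_compound_het([a, b], parental) == PhaseCall.possible_unphased


# --- cohort case examples ---------------------------------------------------


@pytest.fixture(scope="module")
def cohort_results(cohort, canonical_panel, ontology, canonical_icmap):
    return {
        c.case_id: evaluate_case(c, canonical_panel, ontology, canonical_icmap)
        for c in cohort
    }


def test_de_novo_known_dominant_is_definitive(cohort_results):
    r = cohort_results["case_04"]
    assert r.tier == Tier.definitive
    (d,) = r.diagnoses
    assert d.gene == "PTPN11" and d.segregation == "de_novo"
    assert d.assessments[0].variant_class == VariantClass.known_pathogenic


def test_known_dominant_without_parents_is_highly_likely(cohort_results):
    r = cohort_results["case_06"]
    assert r.tier == Tier.highly_likely
    assert r.diagnoses[0].gene == "PROKR2"
    assert r.diagnoses[0].segregation == "unconfirmed"


def test_no_qualifying_variant_is_negative(cohort_results):
    r = cohort_results["case_09"]
    assert r.tier == Tier.negative
    assert r.diagnoses == [] and r.candidates_for_review == []


def test_nonsense_segregating_in_affected_relative_is_definitive(cohort_results):
    r = cohort_results["case_03"]
    assert r.tier == Tier.definitive
    assert r.diagnoses[0].segregation == "affected_relative"


def test_inherited_dominant_probable_missense_reported_vous(cohort_results):
    r = cohort_results["case_07"]
    assert r.tier == Tier.vous
    assert r.diagnoses == []
    (zic1,) = r.candidates_for_review
    assert zic1.gene == "ZIC1" and zic1.variant_class == VariantClass.vous


def test_all_cohort_tiers(cohort_results):
    got = {cid: r.tier for cid, r in cohort_results.items()}
    assert got == EXPECTED_TABLE1_TIERS


# --- evidence monotonicity and degradation properties -----------------------


def _evaluate(case, canonical_panel, ontology, canonical_icmap, **cfg_kwargs):
    return evaluate_case(case, canonical_panel, ontology, canonical_icmap,
                         CaseConfig(**cfg_kwargs) if cfg_kwargs else None)


def test_removing_parental_data_degrades_never_upgrades(
    cohort, canonical_panel, ontology, canonical_icmap
):
    """Stripping trio data from a trans-confirmed recessive case drops the
    tier from definitive to at most highly_likely."""
    rank = {Tier.definitive: 3, Tier.highly_likely: 2, Tier.vous: 1, Tier.negative: 0}
    for cid in ("case_01", "case_02", "case_05"):
        case = copy.deepcopy(next(c for c in cohort if c.case_id == cid))
        case.parental_genotypes = {}
        case.declared_inheritance = {}
        r = _evaluate(case, canonical_panel, ontology, canonical_icmap)
        assert rank[r.tier] <= rank[Tier.highly_likely], cid


def test_adding_known_db_hit_never_lowers_tier(
    cohort, canonical_panel, ontology, canonical_icmap
):
    base = {
        c.case_id: _evaluate(c, canonical_panel, ontology, canonical_icmap).tier
        for c in cohort
    }
    rank = {Tier.definitive: 3, Tier.highly_likely: 2, Tier.vous: 1, Tier.negative: 0}
    for c in cohort:
        if not c.variants:
            continue
        upgraded = copy.deepcopy(c)
        for v in upgraded.variants:
            v.known_pathogenic = True
            v.known_citation = "hypothetical"
        r = _evaluate(upgraded, canonical_panel, ontology, canonical_icmap)
        assert rank[r.tier] >= rank[base[c.case_id]], c.case_id


def test_unphased_probable_pair_is_not_a_diagnosis(
    cohort, canonical_panel, ontology, canonical_icmap
):
    """Two in-silico-probable recessive alleles without trans confirmation and
    without a known/obligatory anchor stay review candidates."""
    case = copy.deepcopy(next(c for c in cohort if c.case_id == "case_02"))
    case.parental_genotypes = {}
    case.declared_inheritance = {}
    r = _evaluate(case, canonical_panel, ontology, canonical_icmap)
    assert r.diagnoses == []
    assert r.tier == Tier.vous
    assert len(r.candidates_for_review) == 2


def test_candidates_never_outside_prioritized_set(
    cohort, canonical_panel, ontology, canonical_icmap
):
    from fetalis.phenotype_prioritizer import prioritize_genes

    for c in cohort:
        r = _evaluate(c, canonical_panel, ontology, canonical_icmap)
        pl = prioritize_genes(canonical_panel, c.findings, canonical_icmap, ontology)
        for a in r.candidates_for_review:
            assert a.gene in pl.prioritized_set


def test_negative_iff_no_diagnoses_and_no_candidates(cohort_results):
    for r in cohort_results.values():
        assert (r.tier == Tier.negative) == (
            not r.diagnoses and not r.candidates_for_review
        )


def test_filter_trace_counts_weakly_decreasing(cohort_results):
    order = [
        "panel_restricted", "phenotype_prioritized", "after_local_frequency",
        "after_international_frequency", "classified_significant",
        "candidates_for_review",
    ]
    for r in cohort_results.values():
        counts = [r.filter_trace[k] for k in order]
        assert counts == sorted(counts, reverse=True)
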