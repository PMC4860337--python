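"""Ontology parsing, information content, Resnik similarity and gene gating.

The brute-force oracle used here climbs parent links recursively on the raw
obonet graph — an independent path from the package's cached ancestor sets.
"""

import math

import obonet
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalis.panel_registry import GeneEntry, GenePanel, Inheritance
from fetalis.phenotype_prioritizer import (
    FindingSet,
    OntologyError,
    compute_ic,
    gene_phenotype_score,
    load_ontology,
    mini_ontology_path,
    prioritize_genes,
    resnik_similarity,
)

# --- loading ---------------------------------------------------------------


def test_bundled_mini_ontology_loads(ontology):
    assert len(ontology) == 40
    assert ontology.labels[ontology.root] == "Phenotypic abnormality"
    # obsolete stanza dropped, alt_id resolves to its primary term
    assert ontology.resolve("HP:0000999") is None
    assert ontology.resolve("HP:0009311") == "HP:0000311"


def test_single_term_file_is_valid(tmp_path):
    p = tmp_path / "one.obo"
    p.write_text("format-version: 1.2\n\n[Term]\nid: HP:0000001\nname: root\n")
    onto = load_ontology(p)
    assert len(onto) == 1 and onto.root == "HP:0000001"


def test_dangling_is_a_target_rejected(tmp_path):
    p = tmp_path / "dangling.obo"
    p.write_text(
        "format-version: 1.2\n\n[Term]\nid: HP:0000001\nname: root\n\n"
        "[Term]\nid: HP:0000002\nname: child\nis_a: HP:0000042\n"
    )
    with pytest.raises(OntologyError, match="HP:0000042"):
        load_ontology(p)


def test_multiple_roots_rejected(tmp_path):
    p = tmp_path / "tworoots.obo"
    p.write_text(
        "format-version: 1.2\n\n[Term]\nid: HP:0000001\nname: a\n\n"
        "[Term]\nid: HP:0000002\nname: b\n"
    )
    with pytest.raises(OntologyError, match="single root"):
        load_ontology(p)


# --- information content ---------------------------------------------------


def _panel(annotations: dict[str, set[str]]) -> GenePanel:
    return GenePanel(
        [GeneEntry(g, "d", Inheritance.AD, frozenset(t)) for g, t in annotations.items()]
    )


@pytest.fixture(scope="module")
def ten_gene_panel():
    # A: vermis-branch only; B: vermis+polydactyly; C: polydactyly only;
    # 7 more genes spread over other branches.
    ann = {
        "A": {"HP:0000111"},
        "B": {"HP:0000111", "HP:0000113"},
        "C": {"HP:0000113"},
        "D": {"HP:0000211"},
        "E": {"HP:0000221"},
        "F": {"HP:0000313"},
        "G": {"HP:0000410"},
        "H": {"HP:0000510"},
        "I": {"HP:0000610"},
        "J": {"HP:0000314"},
    }
    return _panel(ann)


def test_ic_root_is_zero_and_closed_forms(ontology, ten_gene_panel):
    icmap = compute_ic(ontology, ten_gene_panel)
    assert icmap.total_genes == 10
    assert icmap.ic[ontology.root] == pytest.approx(0.0)
    # term annotated to exactly 1 of 10 genes, no annotated descendants
    assert icmap.annotation_counts["HP:0000313"] == 1
    assert icmap.ic["HP:0000313"] == pytest.approx(-math.log(0.1), abs=1e-12)
    # parent union (not sum): children carry {A,B} and {B,C} -> parent count 3
    assert icmap.annotation_counts["HP:0000111"] == 2
    assert icmap.annotation_counts["HP:0000113"] == 2
    assert icmap.annotation_counts["HP:0000110"] == 3
    assert icmap.ic["HP:0000110"] == pytest.approx(-math.log(0.3), abs=1e-12)
    # unannotated term: +inf sentinel
    assert icmap.annotation_counts["HP:0000112"] == 0
    assert math.isinf(icmap.ic["HP:0000112"])


def test_ic_monotone_parent_to_child(ontology, canonical_panel, canonical_icmap):
    for child, parents in ontology.parents.items():
        for parent in parents:
            ci, pi = canonical_icmap.ic[child], canonical_icmap.ic[parent]
            if math.isfinite(ci) and math.isfinite(pi):
                assert ci >= pi - 1e-12


def test_ic_errors_on_unannotated_panel(ontology):
    with pytest.raises(OntologyError):
        compute_ic(ontology, _panel({"G1": set()}))


# --- Resnik similarity -----------------------------------------------------


def _brute_force_ancestors(graph, term):
    out = {term}
    for parent in graph.nodes[term].get("is_a", []):
        out |= _brute_force_ancestors(graph, parent)
    return out


def test_resnik_equals_brute_force_on_all_term_pairs(ontology, canonical_icmap):
    """Exhaustive common-ancestor oracle over every pair of the 40 terms."""
    graph = obonet.read_obo(str(mini_ontology_path()))
    terms = sorted(ontology.terms)
    for a in terms:
        for b in terms:
            common = _brute_force_ancestors(graph, a) & _brute_force_ancestors(graph, b)
            expected = max(
                (canonical_icmap.ic[t] for t in common if math.isfinite(canonical_icmap.ic[t])),
                default=0.0,
            )
            assert resnik_similarity(canonical_icmap, ontology, a, b) == pytest.approx(expected)


def test_resnik_self_root_and_bounds(ontology, canonical_icmap):
    t = "HP:0000313"
    assert resnik_similarity(canonical_icmap, ontology, t, t) == pytest.approx(
        canonical_icmap.ic[t]
    )
    # only common ancestor is the root
    assert resnik_similarity(canonical_icmap, ontology, "HP:0000111", "HP:0000410") == 0.0
    with pytest.raises(OntologyError):
        resnik_similarity(canonical_icmap, ontology, "HP:9999999", t)


@settings(max_examples=100, derandomize=True)
@given(data=st.data())
def test_resnik_symmetric_and_bounded(ontology, canonical_icmap, data):
    terms = sorted(ontology.terms)
    a = data.draw(st.sampled_from(terms))
    b = data.draw(st.sampled_from(terms))
    sab = resnik_similarity(canonical_icmap, ontology, a, b)
    assert sab == resnik_similarity(canonical_icmap, ontology, b, a)
    assert sab >= 0.0
    bound = min(canonical_icmap.ic[a], canonical_icmap.ic[b])
    if math.isfinite(bound):
        assert sab <= bound + 1e-12


# --- gene scoring and prioritization ---------------------------------------


def test_gene_score_is_mean_of_per_finding_maxima(ontology, ten_gene_panel):
    icmap = compute_ic(ontology, ten_gene_panel)
    gene = GeneEntry(
        "X", "d", Inheritance.AD,
        frozenset({"HP:0000111", "HP:0000113", "HP:0000211"}),
    )
    findings = FindingSet(("HP:0000111", "HP:0000221"))
    # enumerate all finding x annotation pairs by hand
    expected_per_finding = []
    for f in findings.terms:
        expected_per_finding.append(
            max(resnik_similarity(icmap, ontology, f, g) for g in gene.phenotype_terms)
        )
    expected = sum(expected_per_finding) / 2
    got = gene_phenotype_score(gene, findings, icmap, ontology)
    assert got == pytest.approx(expected)
    # perfect match: findings equal to the gene's own terms -> mean of self-ICs
    own = FindingSet(("HP:0000111", "HP:0000211"))
    self_ics = [icmap.ic["HP:0000111"], icmap.ic["HP:0000211"]]
    assert gene_phenotype_score(
        GeneEntry("Y", "d", Inheritance.AD, frozenset(own.terms)), own, icmap, ontology
    ) == pytest.approx(sum(self_ics) / 2)


def test_gene_with_no_informative_overlap_scores_zero(ontology, ten_gene_panel):
    icmap = compute_ic(ontology, ten_gene_panel)
    gene = GeneEntry("X", "d", Inheritance.AD, frozenset({"HP:0000111"}))
    findings = FindingSet(("HP:0000410",))  # shares only the root
    assert gene_phenotype_score(gene, findings, icmap, ontology) == 0.0


def test_prioritize_gates_case7_style(ontology, demo_panel, demo_icmap):
    """A cerebellar finding prioritizes the brain-malformation genes and
    excludes the skeletal-only genes."""
    findings = FindingSet(("HP:0000313",))  # Dandy-Walker analog
    pl = prioritize_genes(demo_panel, findings, demo_icmap, ontology)
    assert {"ZIC1", "CHD7"} <= pl.prioritized_set
    assert {"FGFR3", "HOXD13", "PKD1"}.isdisjoint(pl.prioritized_set)


def test_prioritize_tie_break_and_permutation_invariance(ontology, demo_panel, demo_icmap):
    f1 = FindingSet(("HP:0000312", "HP:0000316"))
    f2 = FindingSet(("HP:0000316", "HP:0000312"))
    p1 = prioritize_genes(demo_panel, f1, demo_icmap, ontology)
    p2 = prioritize_genes(demo_panel, f2, demo_icmap, ontology)
    assert p1.ranked == p2.ranked
    assert p1.prioritized_set == p2.prioritized_set
    # ties broken alphabetically
    scores = dict(p1.ranked)
    for (g1, s1), (g2, s2) in zip(p1.ranked, p1.ranked[1:]):
        assert s1 > s2 or (s1 == s2 and g1 < g2)
    assert scores  # sanity


def test_disjoint_findings_empty_prioritized_set(ontology, demo_panel, demo_icmap):
    # no demo gene is annotated under the digestive branch
    pl = prioritize_genes(demo_panel, FindingSet(("HP:0000610",)), demo_icmap, ontology)
    assert pl.prioritized_set == frozenset()
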