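"""Phenotype-ontology semantic similarity and gene prioritization.

Implements the phenotype-driven gene gate: up to three ultrasound-finding
terms are compared against each panel gene's phenotype annotations using
Resnik similarity (information content of the most informative common
ancestor), the kernel at the core of Phenomizer-style ranking. Genes with any
informative overlap (score > 0) form the prioritized subset; downstream
variant evaluation is restricted to it.

Information content is computed from the panel's own gene-term annotations:
ic(t) = -ln(n_t / N) where n_t counts panel genes annotated to t or any
descendant (each gene counted once) and N is the number of annotated panel
genes. The root therefore has ic 0 and unannotated terms get an +inf
sentinel and are excluded from similarity maxima.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

from .panel_registry import GeneEntry, GenePanel

log = logging.getLogger("fetalis.phenotype")


class OntologyError(ValueError):
    """Raised for structurally invalid ontology files."""


@dataclass
class Ontology:
    """Phenotype-term DAG (is_a edges only, child -> parent)."""

    terms: set[str]
    labels: dict[str, str]
    parents: dict[str, set[str]]
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def resolve(self, term: str) -> Optional[str]:
        """Map a term or alt_id to its primary id; ``None`` if unknown."""
        if term in self.terms:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term``, inclusive of the term itself."""
        t = self.resolve(term)
        if t is None:
            raise OntologyError(f"unknown ontology term: {term}")
        cached = self._ancestor_cache.get(t)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [t]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self.parents.get(cur, ()))
        result = frozenset(out)
        self._ancestor_cache[t] = result
        return result

    def label_to_id(self, label: str) -> Optional[str]:
        for t, name in self.labels.items():
            if name == label:
                return t
        return None

    def __len__(self) -> int:
        return len(self.terms)


def load_ontology(obo_file: Path | str) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only ``id``, ``name``, ``alt_id``, ``is_a`` and ``is_obsolete`` are used;
    obsolete terms are dropped, alt_ids map to their primary term, and other
    relationship types (part_of, ...) are ignored. The file must be a
    single-rooted DAG.
    """
    graph = obonet.read_obo(str(obo_file))  # drops obsolete stanzas
    terms: set[str] = set()
    labels: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # node created only by an is_a reference from another stanza
            continue
        terms.add(node)
        labels[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for node in terms:
        for target in graph.nodes[node].get("is_a", []):
            if target not in terms:
                raise OntologyError(
                    f"term {node}: is_a target {target} not defined in file (dangling edge)"
                )
            parents.setdefault(node, set()).add(target)
    sub = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    sub.add_nodes_from(terms)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = next(nx.simple_cycles(sub))
        raise OntologyError(f"ontology contains a cycle through {cycle[0]}")
    roots = sorted(t for t in terms if not parents.get(t))
    if len(roots) != 1:
        raise OntologyError(f"ontology must have a single root, found {roots}")
    onto = Ontology(terms=terms, labels=labels, parents=parents, root=roots[0], alt_ids=alt_ids)
    log.info("loaded ontology: %d terms, root %s (%s)", len(onto), onto.root, labels[onto.root])
    return onto


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------


@dataclass
class ICMap:
    """Per-term information content derived from panel annotations (nats)."""

    ic: dict[str, float]
    annotation_counts: dict[str, int]
    total_genes: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def compute_ic(ontology: Ontology, panel: GenePanel) -> ICMap:
    """Propagate gene annotations up the DAG and derive ic per term.

    A gene annotated to several descendants of a term is counted once at
    that term (set union, not sum).
    """
    gene_sets: dict[str, set[str]] = {t: set() for t in ontology.terms}
    annotated_genes: set[str] = set()
    for entry in panel.entries:
        resolved = {ontology.resolve(t) for t in entry.phenotype_terms}
        resolved.discard(None)
        if not resolved:
            continue
        annotated_genes.add(entry.symbol)
        for t in resolved:
            for anc in ontology.ancestors(t):
                gene_sets[anc].add(entry.symbol)
    total = len(annotated_genes)
    if total == 0:
        raise OntologyError("panel has no genes with resolvable phenotype annotations")
    counts = {t: len(s) for t, s in gene_sets.items()}
    ic = {
        t: (-math.log(c / total) if c > 0 else math.inf)
        for t, c in counts.items()
    }
    return ICMap(ic=ic, annotation_counts=counts, total_genes=total)


def resnik_similarity(icmap: ICMap, ontology: Ontology, a: str, b: str) -> float:
    """IC of the most informative common ancestor of ``a`` and ``b``.

    Both terms are ancestors of themselves; terms with the +inf sentinel
    (zero annotations) are excluded from the maximum. The root (ic 0) is a
    common ancestor of everything, so the result is always >= 0.
    """
    common = ontology.ancestors(a) & ontology.ancestors(b)
    finite = [icmap.ic[t] for t in common if math.isfinite(icmap.ic[t])]
    return max(finite, default=0.0)


# ---------------------------------------------------------------------------
# Finding set and gene scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FindingSet:
    """1-3 user-selected ultrasound-finding terms."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 3:
            raise ValueError(f"a finding set holds 1-3 terms, got {len(self.terms)}")

    @classmethod
    def from_terms(cls, terms: Iterable[str], ontology: Ontology) -> "FindingSet":
        resolved = []
        for t in terms:
            r = ontology.resolve(t) or ontology.label_to_id(t)
            if r is None:
                raise OntologyError(f"finding term {t!r} not in ontology (by id or exact label)")
            resolved.append(r)
        return cls(tuple(resolved))


def gene_phenotype_score(
    gene: GeneEntry, findings: FindingSet, icmap: ICMap, ontology: Ontology
) -> float:
    """One-sided findings->gene relevance score.

    Mean over finding terms of the best Resnik similarity to any of the
    gene's annotation terms. Symmetric in the findings, bounded by the
    findings' own ICs, and insensitive to how many annotations the gene has.
    """
    if not gene.phenotype_terms:
        log.warning("gene %s has no phenotype annotations; score 0", gene.symbol)
        return 0.0
    gene_terms = [t for t in (ontology.resolve(g) for g in gene.phenotype_terms) if t]
    if not gene_terms:
        return 0.0
    per_finding = [
        max(resnik_similarity(icmap, ontology, f, g) for g in gene_terms)
        for f in findings.terms
    ]
    return sum(per_finding) / len(per_finding)


@dataclass
class GenePriorityList:
    ranked: list[tuple[str, float]]  # (symbol, score), score desc / symbol asc
    prioritized_set: frozenset[str]  # genes passing the inclusion rule

    def score_of(self, symbol: str) -> float:
        for s, sc in self.ranked:
            if s == symbol:
                return sc
        return 0.0


def prioritize_genes(
    panel: GenePanel,
    findings: FindingSet,
    icmap: ICMap,
    ontology: Ontology,
    min_score: float = 0.0,
) -> GenePriorityList:
    """Score every panel gene against the findings and gate on score.

    The inclusion rule is permissive — any informative shared ancestor
    (score strictly greater than ``min_score``, default 0) admits the gene;
    variant-level filters downstream do most of the narrowing.
    """
    scores = {
        e.symbol: gene_phenotype_score(e, findings, icmap, ontology) for e in panel.entries
    }
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    prioritized = frozenset(s for s, sc in scores.items() if sc > min_score)
    log.info(
        "phenotype prioritization: %d of %d panel genes prioritized",
        len(prioritized), len(panel),
    )
    return GenePriorityList(ranked=ranked, prioritized_set=prioritized)


def mini_ontology_path() -> Path:
    from importlib import resources

    return Path(resources.files("fetalis").joinpath("data/mini_ontology.obo"))
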