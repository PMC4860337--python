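"""Targeted gene panel and known-pathogenic mutation registry.

The panel defines the *closed gene universe* of the test: variants in genes
outside it are discarded before any interpretation step, which is what makes
incidental findings structurally impossible. Each panel entry carries the
associated disorder, its inheritance mode, and the phenotype-ontology terms
annotated to the gene (the substrate for phenotype-driven prioritization).

Gene symbols are opaque, exact-match, case-sensitive strings: the panel is a
curated artifact and silent alias resolution risks clinical misassignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger("fetalis.panel")

PANEL_COLUMNS = ("symbol", "disorder", "inheritance", "phenotype_terms")
KNOWN_DB_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "hgvs_c", "hgvs_p", "citation")


class PanelValidationError(ValueError):
    """Raised when a panel or known-pathogenic table violates its contract."""


class Inheritance(str, Enum):
    """Mendelian inheritance mode of the gene-disorder pair.

    AD_AR marks dual-mode genes (e.g. EVC2: recessive Ellis-van Creveld
    syndrome and dominant Weyers acrodental dysostosis); the case engine
    evaluates both models for such genes.
    """

    AD = "AD"
    AR = "AR"
    XL = "XL"
    AD_AR = "AD_AR"


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    disorder: str
    inheritance: Inheritance
    phenotype_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelValidationError("gene symbol must be non-empty")


@dataclass
class GenePanel:
    """Ordered, duplicate-free collection of gene entries."""

    entries: list[GeneEntry]
    name: str = "panel"
    version: str = "0"
    _index: dict[str, GeneEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for e in self.entries:
            if e.symbol in self._index:
                raise PanelValidationError(f"duplicate gene symbol in panel: {e.symbol}")
            self._index[e.symbol] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def inheritance_map(self) -> dict[str, Inheritance]:
        return {e.symbol: e.inheritance for e in self.entries}


def _data_rows(path: Path | str) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields) skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_panel(panel_table: Path | str, name: Optional[str] = None) -> GenePanel:
    """Load and validate a gene panel from a TSV file.

    Expected header: ``symbol  disorder  inheritance  phenotype_terms`` with
    phenotype terms semicolon-separated. ``#``-prefixed lines are ignored.
    Row order is preserved.
    """
    rows = _data_rows(panel_table)
    try:
        _, header = next(rows)
    except StopIteration:
        raise PanelValidationError(f"{panel_table}: empty panel file (no header)")
    if tuple(h.strip() for h in header[:4]) != PANEL_COLUMNS:
        raise PanelValidationError(
            f"{panel_table}: expected header columns {PANEL_COLUMNS}, got {header[:4]}"
        )
    entries: list[GeneEntry] = []
    seen: set[str] = set()
    for lineno, fields in rows:
        if len(fields) < 4:
            raise PanelValidationError(f"{panel_table}:{lineno}: expected 4 columns, got {len(fields)}")
        symbol, disorder, inh_code, terms = (f.strip() for f in fields[:4])
        if symbol in seen:
            raise PanelValidationError(f"{panel_table}:{lineno}: duplicate gene symbol {symbol}")
        seen.add(symbol)
        try:
            inh = Inheritance(inh_code)
        except ValueError:
            raise PanelValidationError(
                f"{panel_table}:{lineno}: unknown inheritance code {inh_code!r} "
                f"(expected one of {[m.value for m in Inheritance]})"
            ) from None
        term_set = frozenset(t for t in (s.strip() for s in terms.split(";")) if t)
        entries.append(GeneEntry(symbol, disorder, inh, term_set))
    panel = GenePanel(entries, name=name or Path(panel_table).stem)
    log.info("loaded panel %s: %d genes", panel.name, len(panel))
    return panel


def write_panel(panel: GenePanel, path: Path | str) -> None:
    """Write a panel back to TSV; ``load_panel(write_panel(p))`` is the identity."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in panel.entries:
            terms = ";".join(sorted(e.phenotype_terms))
            fh.write(f"{e.symbol}\t{e.disorder}\t{e.inheritance.value}\t{terms}\n")


def lookup_gene(panel: GenePanel, symbol: str) -> Optional[GeneEntry]:
    """Exact, case-sensitive symbol lookup; ``None`` when absent."""
    return panel._index.get(symbol)


# ---------------------------------------------------------------------------
# Known-pathogenic mutation table
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-normalize a variant to its minimal left-anchored form.

    Shared trailing bases are trimmed first, then shared leading bases
    (keeping at least one base on each allele, advancing ``pos``), and
    alleles are uppercased. This is reference-free normalization; left
    shifting across repeat tracts would need the reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class KnownPathogenicRecord:
    gene: str
    hgvs_c: str
    hgvs_p: str
    citation: str
    dbsnp: Optional[str] = None


@dataclass
class KnownPathogenicDB:
    """Literature/database-documented pathogenic alleles, keyed on normalized
    genomic coordinates (HGVS strings are carried for reporting only)."""

    records: dict[VariantKey, KnownPathogenicRecord]
    build: str = "unspecified"

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> Optional[KnownPathogenicRecord]:
        return self.records.get(normalize_variant_key(chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self.records)


def load_known_pathogenic(table: Path | str) -> KnownPathogenicDB:
    """Load the known-pathogenic table (TSV, 1-based VCF-convention positions).

    Columns: ``chrom pos ref alt gene hgvs_c hgvs_p citation [dbsnp]``.
    A ``#build=<tag>`` comment line sets the genome-build tag.
    """
    build = "unspecified"
    with open(table, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#build="):
                build = line.strip().split("=", 1)[1]
    records: dict[VariantKey, KnownPathogenicRecord] = {}
    rows = _data_rows(table)
    _, header = next(rows)
    if tuple(h.strip() for h in header[: len(KNOWN_DB_COLUMNS)]) != KNOWN_DB_COLUMNS:
        raise PanelValidationError(
            f"{table}: expected header columns {KNOWN_DB_COLUMNS}, got {header}"
        )
    for lineno, fields in rows:
        if len(fields) < 8:
            raise PanelValidationError(f"{table}:{lineno}: expected >=8 columns")
        chrom, pos_s, ref, alt, gene, hgvs_c, hgvs_p, citation = (f.strip() for f in fields[:8])
        dbsnp = fields[8].strip() if len(fields) > 8 and fields[8].strip() else None
        try:
            pos = int(pos_s)
        except ValueError:
            raise PanelValidationError(
                f"{table}:{lineno}: malformed position {pos_s!r} (not an integer)"
            ) from None
        key = normalize_variant_key(chrom, pos, ref, alt)
        if key in records:
            raise PanelValidationError(
                f"{table}:{lineno}: duplicate known-pathogenic key {key}"
            )
        records[key] = KnownPathogenicRecord(gene, hgvs_c, hgvs_p, citation, dbsnp)
    db = KnownPathogenicDB(records, build=build)
    log.info("loaded known-pathogenic table: %d records (build %s)", len(db), build)
    return db


def validate_panel_terms(panel: GenePanel, ontology) -> None:
    """Cross-validate that every panel phenotype term resolves in the ontology.

    Run once at pipeline start; raises :class:`PanelValidationError` naming the
    first offending gene/term pair.
    """
    for e in panel.entries:
        for t in e.phenotype_terms:
            if ontology.resolve(t) is None:
                raise PanelValidationError(
                    f"panel gene {e.symbol}: phenotype term {t} not in ontology"
                )


def canonical_panel_path() -> Path:
    """Path to the bundled 758-gene panel file.

    The bundled file is a synthetic stand-in for the curated clinical list:
    16 exemplar genes with literature-consistent disorder/inheritance/phenotype
    annotations plus generated placeholder entries, 758 in total.
    """
    return Path(resources.files("fetalis").joinpath("data/panel_758_synthetic.tsv"))


def load_canonical_panel() -> GenePanel:
    """Load the bundled canonical 758-gene panel."""
    return load_panel(canonical_panel_path(), name="fetalis-758-synthetic")
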