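"""Variant ingestion and annotation joining.

Reads proband (and optional parental) calls from VCF, decomposes
multi-allelic records, parsimony-normalizes alleles, joins the annotation
sidecar table (gene, consequence, HGVS, in-silico predictor scores, splice
prediction), attaches per-source allele frequencies and known-pathogenic
status, and restricts the variant set to the panel's gene universe.

Coordinates are 1-based VCF convention throughout.

Sidecar conventions: ``dist_to_exon`` is the signed distance to the nearest
exon boundary — negative values are intronic base offsets (-1, -2 are the
canonical splice dinucleotide), 0 is the first/last base of an exon,
positive values are interior exonic offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

from cyvcf2 import VCF

from .panel_registry import (
    GenePanel,
    KnownPathogenicDB,
    VariantKey,
    normalize_variant_key,
)

log = logging.getLogger("fetalis.variants")

SIDECAR_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "hgvs_c", "hgvs_p", "predictors", "splice_pred", "dist_to_exon",
)


class Zygosity(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    canonical_splice = "canonical_splice"
    splice_region = "splice_region"
    synonymous = "synonymous"
    other = "other"


#: sidecar consequence-string normalization (VEP/SO-style labels included)
_CONSEQUENCE_ALIASES = {
    "missense": Consequence.missense,
    "missense_variant": Consequence.missense,
    "nonsense": Consequence.nonsense,
    "stop_gained": Consequence.nonsense,
    "frameshift": Consequence.frameshift,
    "frameshift_variant": Consequence.frameshift,
    "inframe_indel": Consequence.inframe_indel,
    "inframe_insertion": Consequence.inframe_indel,
    "inframe_deletion": Consequence.inframe_indel,
    "canonical_splice": Consequence.canonical_splice,
    "splice_donor_variant": Consequence.canonical_splice,
    "splice_acceptor_variant": Consequence.canonical_splice,
    "splice_region": Consequence.splice_region,
    "splice_region_variant": Consequence.splice_region,
    "synonymous": Consequence.synonymous,
    "synonymous_variant": Consequence.synonymous,
    "other": Consequence.other,
}


class VcfError(ValueError):
    pass


@dataclass
class Variant:
    """One decomposed, normalized called variant with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, Zygosity]
    depth: dict[str, int] = field(default_factory=dict)
    gq: dict[str, int] = field(default_factory=dict)
    hemizygous: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VcfError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantAnnotation:
    gene: str
    consequence: Consequence
    hgvs_c: str = ""
    hgvs_p: str = ""
    predictor_scores: dict[str, float] = field(default_factory=dict)
    splice_effect_predicted: bool = False
    distance_to_exon_boundary: Optional[int] = None


@dataclass
class AnnotatedVariant:
    variant: Variant
    annotation: VariantAnnotation
    frequencies: dict[str, float] = field(default_factory=dict)
    freq_missing_sources: frozenset[str] = frozenset()
    known_pathogenic: bool = False
    known_citation: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def gene(self) -> str:
        return self.annotation.gene


def _zygosity_for_alt(alleles: list[int], alt_index: int) -> Zygosity:
    called = [a for a in alleles if a >= 0]
    if not called:
        return Zygosity.missing
    n_alt = sum(1 for a in called if a == alt_index)
    if n_alt == 0:
        return Zygosity.hom_ref
    if n_alt == len(called) and len(called) > 1:
        return Zygosity.hom_alt
    if len(called) == 1:  # haploid call carrying the alt
        return Zygosity.hom_alt
    return Zygosity.het


def read_vcf(path: Path | str, sample_names: Sequence[str]) -> list[Variant]:
    """Read a VCF into decomposed, normalized :class:`Variant` records.

    Multi-allelic sites become one record per alt allele (a 1/2 het yields
    two het records). Records in which no requested sample carries the alt
    allele (all hom_ref or missing) are dropped.
    """
    vcf = VCF(str(path))
    missing = [s for s in sample_names if s not in vcf.samples]
    if missing:
        raise VcfError(
            f"{path}: sample(s) {missing} not in VCF; available samples: {list(vcf.samples)}"
        )
    idx = {s: vcf.samples.index(s) for s in sample_names}
    out: list[Variant] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...] per sample
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        for k, alt in enumerate(rec.ALT, start=1):
            genotypes: dict[str, Zygosity] = {}
            depth: dict[str, int] = {}
            gqs: dict[str, int] = {}
            for s, i in idx.items():
                alleles = [a for a in gts[i][:-1]]
                genotypes[s] = _zygosity_for_alt(alleles, k)
                if dp is not None and int(dp[i][0]) >= 0:
                    depth[s] = int(dp[i][0])
                if gq is not None and int(gq[i][0]) >= 0:
                    gqs[s] = int(gq[i][0])
            if not any(z in (Zygosity.het, Zygosity.hom_alt) for z in genotypes.values()):
                continue
            chrom, pos, ref, nalt = normalize_variant_key(rec.CHROM, rec.POS, rec.REF, alt)
            out.append(Variant(chrom, pos, ref, nalt, genotypes, depth, gqs))
    log.info("read %d variants for samples %s from %s", len(out), list(sample_names), path)
    return out


def normalize_hemizygous(variants: list[Variant], proband: str, fetal_sex: str) -> None:
    """Male X-chromosome calls: treat het calls as hemizygous hom_alt.

    Variant callers often emit diploid genotypes on chrX for males; a single
    alt allele there is effectively homozygous for recessive logic.
    """
    if fetal_sex != "male":
        return
    for v in variants:
        if v.chrom in ("X", "chrX") and v.genotypes.get(proband) == Zygosity.het:
            v.genotypes[proband] = Zygosity.hom_alt
            v.hemizygous = True


def parse_predictors(spec: str) -> dict[str, float]:
    """Parse ``name=score;name=score`` predictor strings, clamping to [0,1]."""
    scores: dict[str, float] = {}
    for part in spec.split(";"):
        part = part.strip()
        if not part or part == ".":
            continue
        name, _, val = part.partition("=")
        scores[name.strip()] = min(1.0, max(0.0, float(val)))
    return scores


def classify_consequence(annotation: VariantAnnotation) -> Consequence:
    """Normalize the annotated consequence, enforcing the ±2 splice rule.

    An intronic variant within the two bases flanking an exon
    (``distance_to_exon_boundary`` of -1 or -2) is canonical_splice
    regardless of the sidecar label. Exonic boundary bases (distance 0)
    keep their coding consequence; a predicted splice effect there is the
    classifier's concern.
    """
    cons = annotation.consequence
    d = annotation.distance_to_exon_boundary
    if d is not None and -2 <= d <= -1:
        return Consequence.canonical_splice
    return cons


def _parse_sidecar_row(fields: list[str], src: str, lineno: int) -> tuple[VariantKey, VariantAnnotation]:
    if len(fields) < len(SIDECAR_COLUMNS):
        raise VcfError(f"{src}:{lineno}: expected {len(SIDECAR_COLUMNS)} columns")
    chrom, pos_s, ref, alt, gene, cons_s, hgvs_c, hgvs_p, preds, splice_s, dist_s = (
        f.strip() for f in fields[:11]
    )
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfError(f"{src}:{lineno}: malformed position {pos_s!r}") from None
    cons = _CONSEQUENCE_ALIASES.get(cons_s)
    if cons is None:
        log.warning("%s:%d: unrecognized consequence %r mapped to 'other'", src, lineno, cons_s)
        cons = Consequence.other
    dist = None if dist_s in (".", "") else int(dist_s)
    ann = VariantAnnotation(
        gene=gene,
        consequence=cons,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        predictor_scores=parse_predictors(preds),
        splice_effect_predicted=splice_s in ("1", "true", "True", "yes"),
        distance_to_exon_boundary=dist,
    )
    ann.consequence = classify_consequence(ann)
    return normalize_variant_key(chrom, pos, ref, alt), ann


def load_sidecar(path: Path | str) -> dict[VariantKey, VariantAnnotation]:
    """Load the annotation sidecar TSV keyed on normalized (chrom,pos,ref,alt)."""
    table: dict[VariantKey, VariantAnnotation] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(f.strip() for f in fields[:11]) != SIDECAR_COLUMNS:
                    raise VcfError(f"{path}: expected sidecar header {SIDECAR_COLUMNS}")
                header_seen = True
                continue
            key, ann = _parse_sidecar_row(fields, str(path), lineno)
            if key in table:
                raise VcfError(f"{path}:{lineno}: duplicate sidecar key {key}")
            table[key] = ann
    return table


def load_frequency_table(path: Path | str) -> dict[VariantKey, float]:
    """Load one allele-frequency source: TSV ``chrom pos ref alt af``."""
    table: dict[VariantKey, float] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                continue
            chrom, pos, ref, alt, af = (f.strip() for f in fields[:5])
            table[normalize_variant_key(chrom, int(pos), ref, alt)] = float(af)
    return table


@dataclass
class AttachAudit:
    unannotated: list[VariantKey] = field(default_factory=list)
    orphan_sidecar_keys: list[VariantKey] = field(default_factory=list)


def attach_annotations(
    variants: list[Variant],
    sidecar: Path | str | dict[VariantKey, VariantAnnotation],
    known_db: KnownPathogenicDB,
    freq_tables: dict[str, dict[VariantKey, float]],
) -> tuple[list[AnnotatedVariant], AttachAudit]:
    """Join variants with sidecar annotations, frequencies, and known-db hits.

    Variants with no sidecar row are routed to the audit's ``unannotated``
    list (they cannot be interpreted without a gene/consequence). A frequency
    absent from a source is treated as 0.0 downstream but the source is
    recorded in ``freq_missing_sources`` so novel and rare are
    distinguishable in reports.
    """
    table = sidecar if isinstance(sidecar, dict) else load_sidecar(sidecar)
    audit = AttachAudit()
    variant_keys = {v.key for v in variants}
    audit.orphan_sidecar_keys = sorted(k for k in table if k not in variant_keys)
    for k in audit.orphan_sidecar_keys:
        log.warning("sidecar row %s matches no variant", k)
    out: list[AnnotatedVariant] = []
    for v in variants:
        ann = table.get(v.key)
        if ann is None:
            audit.unannotated.append(v.key)
            continue
        freqs: dict[str, float] = {}
        missing: set[str] = set()
        for source, tab in freq_tables.items():
            af = tab.get(v.key)
            if af is None:
                missing.add(source)
            else:
                freqs[source] = af
        hit = known_db.lookup(*v.key)
        out.append(
            AnnotatedVariant(
                variant=v,
                annotation=ann,
                frequencies=freqs,
                freq_missing_sources=frozenset(missing),
                known_pathogenic=hit is not None,
                known_citation=hit.citation if hit else None,
            )
        )
    if audit.unannotated:
        log.warning("%d variants had no sidecar annotation", len(audit.unannotated))
    return out, audit


def restrict_to_panel(annotated: list[AnnotatedVariant], panel: GenePanel) -> list[AnnotatedVariant]:
    """Drop every variant whose gene is outside the panel universe.

    This is the structural no-incidental-findings guarantee: nothing outside
    the closed gene list can reach interpretation. Idempotent; preserves
    input order.
    """
    kept = [v for v in annotated if v.gene in panel]
    log.info(
        "panel restriction: %d of %d variants in panel genes (%d discarded)",
        len(kept), len(annotated), len(annotated) - len(kept),
    )
    return kept
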