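"""Offline fixtures: the 14-case validation cohort, a miniature phenotype
ontology with a 16-gene demo panel, and a seeded synthetic case generator.

All genomic coordinates in this module are synthetic placeholders on
toy loci (the printed HGVS strings are authoritative for identity; no
reference genome is downloaded or shipped). The cohort encodes, case by
case, the variants, zygosities, parental carrier states and known-pathogenic
status of the published 14-fetus validation series, so the full pipeline is
exercisable with no network access.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

from .case_engine import CaseInput, ParentalGenotype, Sex, Tier
from .panel_registry import (
    GeneEntry,
    GenePanel,
    Inheritance,
    KnownPathogenicDB,
    KnownPathogenicRecord,
    VariantKey,
    canonical_panel_path,
    load_canonical_panel,
)
from .phenotype_prioritizer import FindingSet, Ontology, load_ontology, mini_ontology_path
from .variant_model import (
    AnnotatedVariant,
    Consequence,
    Variant,
    VariantAnnotation,
    Zygosity,
    classify_consequence,
)

# ---------------------------------------------------------------------------
# Curated exemplar genes (synthetic loci; disorder/inheritance/phenotype
# annotations consistent with the published case series)
# ---------------------------------------------------------------------------

def _terms(*nums: int) -> frozenset[str]:
    return frozenset(f"HP:{n:07d}" for n in nums)


#: symbol -> (chrom, locus base position, disorder, inheritance, phenotype terms)
CURATED_GENES: dict[str, tuple[str, int, str, Inheritance, frozenset[str]]] = {
    "EVC2": ("4", 5_600_000, "Ellis-van Creveld syndrome / Weyers acrodental dysostosis",
             Inheritance.AD_AR, _terms(111, 113, 114, 117, 121, 210)),
    "NEB": ("2", 152_300_000, "Nemaline myopathy 2",
            Inheritance.AR, _terms(116, 321, 322, 510)),
    "COL3A1": ("2", 189_800_000, "Ehlers-Danlos syndrome IV",
               Inheritance.AD, _terms(115, 113)),
    "PTPN11": ("12", 112_850_000, "Noonan syndrome 1",
               Inheritance.AD, _terms(222, 221, 210)),
    "ASS1": ("9", 133_320_000, "Citrullinemia",
             Inheritance.AR, _terms(313, 315)),
    "PROKR2": ("20", 5_280_000, "Kallmann syndrome",
               Inheritance.AD, _terms(211, 210)),
    "ZIC1": ("3", 147_100_000, "Craniosynostosis with structural brain malformations",
             Inheritance.AD, _terms(312, 313, 316, 140)),
    "CHD7": ("8", 61_600_000, "CHARGE-spectrum disorder",
             Inheritance.AD_AR, _terms(312, 311, 210, 430)),
    "FGFR3": ("4", 1_790_000, "Thanatophoric dysplasia",
              Inheritance.AD, _terms(122, 121, 130)),
    "DYNC2H1": ("11", 103_000_000, "Short-rib thoracic dysplasia",
                Inheritance.AR, _terms(111, 121, 122)),
    "HOXD13": ("2", 176_950_000, "Synpolydactyly",
               Inheritance.AD, _terms(111, 117, 113)),
    "PKD1": ("16", 2_130_000, "Polycystic kidney disease",
             Inheritance.AD, _terms(410)),
    "HNF1B": ("17", 36_040_000, "Renal cysts and diabetes syndrome",
              Inheritance.AD, _terms(410)),
    "DHCR7": ("11", 71_140_000, "Smith-Lemli-Opitz syndrome",
              Inheritance.AR, _terms(420, 111, 510, 430)),
    "TTN": ("2", 179_390_000, "Congenital titinopathy",
            Inheritance.AR, _terms(322, 116, 321)),
    "L1CAM": ("X", 153_860_000, "X-linked hydrocephalus",
              Inheritance.XL, _terms(314, 315)),
}


def demo_panel() -> GenePanel:
    """The 16-gene demonstration panel used by the mini-ontology fixtures."""
    entries = [
        GeneEntry(sym, spec[2], spec[3], spec[4]) for sym, spec in CURATED_GENES.items()
    ]
    return GenePanel(entries, name="fetalis-demo-16", version="1")


def mini_ontology() -> tuple[Ontology, GenePanel]:
    """Bundled ~40-term ontology plus the matching 16-gene demo panel."""
    return load_ontology(mini_ontology_path()), demo_panel()


def gene_locus(panel: GenePanel, symbol: str) -> tuple[str, int]:
    """Synthetic (chrom, base) locus for any panel gene, curated or placeholder."""
    if symbol in CURATED_GENES:
        chrom, base, *_ = CURATED_GENES[symbol]
        return chrom, base
    i = panel.symbols().index(symbol)
    return str(i % 22 + 1), 10_000_000 + (i // 22) * 1_000_000


# ---------------------------------------------------------------------------
# Known-pathogenic database fixture
# ---------------------------------------------------------------------------


def _locus(sym: str) -> tuple[str, int]:
    chrom, base, *_ = CURATED_GENES[sym]
    return chrom, base


def known_pathogenic_db() -> KnownPathogenicDB:
    """Known-pathogenic alleles appearing in the validation cohort."""
    entries = [
        ("PTPN11", 181, "G", "A", "c.181G>A", "p.D61N", "rs397507510", "rs397507510"),
        ("ASS1", 971, "G", "T", "c.971G>T", "p.G324V", "lit:citrullinemia", None),
        ("PROKR2", 518, "T", "G", "c.518T>G", "p.L173R", "lit:kallmann", None),
    ]
    records: dict[VariantKey, KnownPathogenicRecord] = {}
    for gene, off, ref, alt, hc, hp, cite, dbsnp in entries:
        chrom, base = _locus(gene)
        records[(chrom, base + off, ref, alt)] = KnownPathogenicRecord(gene, hc, hp, cite, dbsnp)
    return KnownPathogenicDB(records, build="synthetic-toy")


# ---------------------------------------------------------------------------
# Variant definitions and builders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantDef:
    """Declarative single-variant fixture spec, expanded both to in-memory
    pipeline objects and to VCF/sidecar/frequency-table files."""

    gene: str
    offset: int
    ref: str
    alt: str
    consequence: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    predictors: tuple[tuple[str, float], ...] = ()
    splice_pred: bool = False
    dist_to_exon: Optional[int] = 50
    zygosity: Zygosity = Zygosity.het
    maternal: Optional[bool] = None  # None = parent unavailable
    paternal: Optional[bool] = None
    frequencies: tuple[tuple[str, float], ...] = ()
    segregation_confirmed: bool = False

    def key(self, panel: GenePanel) -> VariantKey:
        chrom, base = gene_locus(panel, self.gene)
        return (chrom, base + self.offset, self.ref, self.alt)


def _build_annotated(vd: VariantDef, panel: GenePanel, known_db: KnownPathogenicDB) -> AnnotatedVariant:
    chrom, pos, ref, alt = vd.key(panel)
    genotypes = {"PROBAND": vd.zygosity}
    if vd.maternal is not None:
        genotypes["MOTHER"] = Zygosity.het if vd.maternal else Zygosity.hom_ref
    if vd.paternal is not None:
        genotypes["FATHER"] = Zygosity.het if vd.paternal else Zygosity.hom_ref
    ann = VariantAnnotation(
        gene=vd.gene,
        consequence=Consequence(vd.consequence),
        hgvs_c=vd.hgvs_c,
        hgvs_p=vd.hgvs_p,
        predictor_scores=dict(vd.predictors),
        splice_effect_predicted=vd.splice_pred,
        distance_to_exon_boundary=vd.dist_to_exon,
    )
    ann.consequence = classify_consequence(ann)
    hit = known_db.lookup(chrom, pos, ref, alt)
    freqs = dict(vd.frequencies)
    all_sources = {"local", "intl_exac"}
    return AnnotatedVariant(
        variant=Variant(chrom, pos, ref, alt, genotypes),
        annotation=ann,
        frequencies=freqs,
        freq_missing_sources=frozenset(all_sources - set(freqs)),
        known_pathogenic=hit is not None,
        known_citation=hit.citation if hit else None,
    )


@dataclass
class CaseDef:
    case_id: str
    findings: tuple[str, ...]
    variants: tuple[VariantDef, ...]
    fetal_sex: Sex = Sex.unknown
    family_history: bool = False
    notes: dict[str, object] = field(default_factory=dict)


def _case_input(cd: CaseDef, panel: GenePanel, ontology: Ontology,
                known_db: KnownPathogenicDB) -> CaseInput:
    annotated = [_build_annotated(vd, panel, known_db) for vd in cd.variants]
    parental: dict[VariantKey, ParentalGenotype] = {}
    declared: dict[VariantKey, str] = {}
    confirmed: set[VariantKey] = set()
    for vd, av in zip(cd.variants, annotated):
        if vd.maternal is not None or vd.paternal is not None:
            parental[av.key] = ParentalGenotype(vd.maternal, vd.paternal)
        if vd.maternal:
            declared[av.key] = "maternal"
        elif vd.paternal:
            declared[av.key] = "paternal"
        if vd.segregation_confirmed:
            confirmed.add(av.key)
    return CaseInput(
        case_id=cd.case_id,
        findings=FindingSet.from_terms(cd.findings, ontology),
        variants=annotated,
        parental_genotypes=parental,
        fetal_sex=cd.fetal_sex,
        family_history_flag=cd.family_history,
        segregation_confirmed=frozenset(confirmed),
        declared_inheritance=declared,
        notes=dict(cd.notes),
    )


# ---------------------------------------------------------------------------
# The 14-case validation cohort
# ---------------------------------------------------------------------------


def _f(*nums: int) -> tuple[str, ...]:
    return tuple(f"HP:{n:07d}" for n in nums)


def table1_case_defs() -> list[CaseDef]:
    """Declarative encoding of the published 14-case series."""
    return [
        # Case 1 — abortus, multiple limb deformities: EVC2 compound het,
        # both missense; one probable by score, one by predicted disruption
        # of an exon-boundary acceptor site. Trans confirmed in parents.
        CaseDef(
            "case_01", _f(111, 113, 114),
            (
                VariantDef("EVC2", 2776, "G", "A", "missense", "c.2776G>A", "p.E926K",
                           (("polyphen", 0.72), ("sift_inv", 0.76)),
                           dist_to_exon=120, maternal=False, paternal=True,
                           frequencies=(("intl_exac", 1.647e-05),)),
                VariantDef("EVC2", 707, "T", "C", "missense", "c.707T>C", "p.V236A",
                           (("polyphen", 0.10), ("sift_inv", 0.20)),
                           splice_pred=True, dist_to_exon=0,
                           maternal=True, paternal=False,
                           frequencies=(("intl_exac", 2.48e-05),)),
            ),
            fetal_sex=Sex.male,
        ),
        # Case 2 — abortus, IUGR/contractures/decreased movements: NEB
        # compound het, both probable-pathogenic missense, parents carriers.
        CaseDef(
            "case_02", _f(116, 321, 510),
            (
                VariantDef("NEB", 11060, "C", "T", "missense", "c.11060C>T", "p.A3687V",
                           (("polyphen", 0.85), ("sift_inv", 0.83)),
                           maternal=True, paternal=False),
                VariantDef("NEB", 11333, "T", "C", "missense", "c.11333T>C", "p.I3778T",
                           (("polyphen", 0.80), ("sift_inv", 0.82)),
                           maternal=False, paternal=True,
                           frequencies=(("intl_exac", 9.113e-05),)),
            ),
            family_history=True,
        ),
        # Case 3 — abortus, right-limb defects: COL3A1 nonsense het,
        # paternally inherited, segregating with disease in an affected uncle.
        CaseDef(
            "case_03", _f(115, 113),
            (
                VariantDef("COL3A1", 811, "C", "T", "nonsense", "c.811C>T", "p.R271X",
                           maternal=False, paternal=True, segregation_confirmed=True),
            ),
        ),
        # Case 4 — NT 4.8 mm + cystic hygroma: de novo known-pathogenic PTPN11.
        CaseDef(
            "case_04", _f(222, 221),
            (
                VariantDef("PTPN11", 181, "G", "A", "missense", "c.181G>A", "p.D61N",
                           (("polyphen", 0.95), ("sift_inv", 0.97)),
                           maternal=False, paternal=False),
            ),
            fetal_sex=Sex.male,
        ),
        # Case 5 — brain MRI abnormalities: ASS1 compound het, one known
        # pathogenic (paternal) + one novel probable at EMA score 75 (maternal).
        CaseDef(
            "case_05", _f(313, 315),
            (
                VariantDef("ASS1", 725, "C", "T", "missense", "c.725C>T", "p.T242I",
                           (("polyphen", 0.70), ("sift_inv", 0.80)),
                           maternal=True, paternal=False),
                VariantDef("ASS1", 971, "G", "T", "missense", "c.971G>T", "p.G324V",
                           (("polyphen", 0.90), ("sift_inv", 0.92)),
                           maternal=False, paternal=True),
            ),
            fetal_sex=Sex.female,
            family_history=True,
        ),
        # Case 6 — ventricular septal defect: known-pathogenic PROKR2 het,
        # parents unavailable for testing.
        CaseDef(
            "case_06", _f(211),
            (
                VariantDef("PROKR2", 518, "T", "G", "missense", "c.518T>G", "p.L173R",
                           (("polyphen", 0.88), ("sift_inv", 0.90))),
            ),
        ),
        # Case 7 — cerebellar vermis rotation + enlarged cisterna magna:
        # maternally inherited probable ZIC1 missense (reported VOUS) plus a
        # CHD7 missense dismissed for its common population frequency.
        CaseDef(
            "case_07", _f(312, 316),
            (
                VariantDef("ZIC1", 1208, "C", "A", "missense", "c.1208C>A", "p.S403Y",
                           (("polyphen", 0.74), ("sift_inv", 0.70)),
                           maternal=True, paternal=None),
                VariantDef("CHD7", 1375, "C", "T", "missense", "c.1375C>T", "p.R459C",
                           (("polyphen", 0.60), ("sift_inv", 0.62)),
                           frequencies=(("intl_exac", 0.02),)),
            ),
            family_history=True,
        ),
        # Cases 8-14 — no pathogenic mutation: background variants only,
        # each either common in population sources or benign by consequence.
        CaseDef(
            "case_08", _f(510, 130, 121),
            (
                VariantDef("FGFR3", 1138, "G", "A", "missense", "c.1138G>A", "p.G380R?",
                           (("polyphen", 0.40),),
                           frequencies=(("local", 0.02), ("intl_exac", 0.03))),
                VariantDef("NEB", 9000, "C", "T", "synonymous", "c.9000C>T", "p.=",
                           frequencies=(("intl_exac", 0.001),)),
            ),
        ),
        CaseDef(
            "case_09", _f(112),
            (
                VariantDef("HOXD13", 820, "A", "G", "missense", "c.820A>G", "p.I274V",
                           (("polyphen", 0.30),),
                           frequencies=(("intl_exac", 0.05),)),
            ),
        ),
        CaseDef(
            "case_10", _f(111),
            (
                VariantDef("EVC2", 1500, "G", "A", "synonymous", "c.1500G>A", "p.="),
                VariantDef("DYNC2H1", 5000, "T", "C", "missense", "c.5000T>C", "p.L1667P",
                           (("polyphen", 0.35),),
                           frequencies=(("intl_exac", 0.01),)),
            ),
        ),
        CaseDef(
            "case_11", _f(410, 610, 121),
            (
                VariantDef("PKD1", 7300, "C", "G", "missense", "c.7300C>G", "p.P2434A",
                           (("polyphen", 0.25),),
                           frequencies=(("local", 0.03), ("intl_exac", 0.02))),
                VariantDef("FGFR3", 600, "C", "T", "synonymous", "c.600C>T", "p.=",
                           frequencies=(("intl_exac", 0.1),)),
            ),
        ),
        CaseDef(
            "case_12", _f(410),
            (
                VariantDef("HNF1B", 900, "G", "T", "missense", "c.900G>T", "p.K300N",
                           (("polyphen", 0.45),),
                           frequencies=(("intl_exac", 0.02),)),
            ),
            notes={"twin_pregnancy": True, "twin_sibling": "case_13"},
        ),
        CaseDef(
            "case_13", _f(121, 610),
            (
                VariantDef("FGFR3", 2000, "A", "C", "missense", "c.2000A>C", "p.K667T",
                           (("polyphen", 0.20),),
                           frequencies=(("intl_exac", 0.04),)),
            ),
            notes={"twin_pregnancy": True, "twin_sibling": "case_12"},
        ),
        CaseDef(
            "case_14", _f(222, 221),
            (
                VariantDef("PTPN11", 500, "G", "A", "synonymous", "c.500G>A", "p.="),
            ),
        ),
    ]


#: expected reporting tier per case, as published
EXPECTED_TABLE1_TIERS: dict[str, Tier] = {
    "case_01": Tier.definitive,
    "case_02": Tier.definitive,
    "case_03": Tier.definitive,
    "case_04": Tier.definitive,
    "case_05": Tier.definitive,
    "case_06": Tier.highly_likely,
    "case_07": Tier.vous,
    **{f"case_{i:02d}": Tier.negative for i in range(8, 15)},
}


def table1_cohort(
    panel: Optional[GenePanel] = None,
    ontology: Optional[Ontology] = None,
) -> list[CaseInput]:
    """The 14 validation cases as ready-to-evaluate :class:`CaseInput` objects."""
    panel = panel or load_canonical_panel()
    ontology = ontology or load_ontology(mini_ontology_path())
    db = known_pathogenic_db()
    return [_case_input(cd, panel, ontology, db) for cd in table1_case_defs()]


# ---------------------------------------------------------------------------
# Seeded synthetic case generator
# ---------------------------------------------------------------------------


class ScenarioMode(str, Enum):
    ad_known = "ad_known"
    ad_obligatory = "ad_obligatory"
    ad_denovo = "ad_denovo"
    ar_compound_het = "ar_compound_het"
    ar_hom = "ar_hom"
    vous_only = "vous_only"
    negative = "negative"


@dataclass
class Scenario:
    mode: ScenarioMode
    seed: int
    n_background_variants: int = 200
    panel: Optional[GenePanel] = None

    def __post_init__(self) -> None:
        if self.n_background_variants < 0:
            raise ValueError("n_background_variants must be >= 0")


@dataclass
class ScenarioTruth:
    tier: Tier
    causal_keys: frozenset[VariantKey]
    causal_gene: Optional[str]


_MODE_SPIKES: dict[ScenarioMode, tuple[tuple[VariantDef, ...], tuple[str, ...], Tier]] = {
    ScenarioMode.ad_known: (
        (VariantDef("PROKR2", 518, "T", "G", "missense", "c.518T>G", "p.L173R",
                    (("polyphen", 0.88),)),),
        _f(211), Tier.highly_likely,
    ),
    ScenarioMode.ad_obligatory: (
        (VariantDef("COL3A1", 811, "C", "T", "nonsense", "c.811C>T", "p.R271X"),),
        _f(115, 113), Tier.highly_likely,
    ),
    ScenarioMode.ad_denovo: (
        (VariantDef("PTPN11", 181, "G", "A", "missense", "c.181G>A", "p.D61N",
                    (("polyphen", 0.95),), maternal=False, paternal=False),),
        _f(222, 221), Tier.definitive,
    ),
    ScenarioMode.ar_compound_het: (
        (VariantDef("NEB", 11060, "C", "T", "missense", "c.11060C>T", "p.A3687V",
                    (("polyphen", 0.85), ("sift_inv", 0.83)), maternal=True, paternal=False),
         VariantDef("NEB", 11333, "T", "C", "missense", "c.11333T>C", "p.I3778T",
                    (("polyphen", 0.80), ("sift_inv", 0.82)), maternal=False, paternal=True,
                    frequencies=(("intl_exac", 9.113e-05),))),
        _f(116, 321, 510), Tier.definitive,
    ),
    ScenarioMode.ar_hom: (
        (VariantDef("DHCR7", 964, "G", "A", "nonsense", "c.964G>A", "p.W322X",
                    zygosity=Zygosity.hom_alt, maternal=True, paternal=True),),
        _f(420, 111), Tier.definitive,
    ),
    ScenarioMode.vous_only: (
        (VariantDef("ZIC1", 1208, "C", "A", "missense", "c.1208C>A", "p.S403Y",
                    (("polyphen", 0.74), ("sift_inv", 0.70)), maternal=True, paternal=False),),
        _f(312, 316), Tier.vous,
    ),
    ScenarioMode.negative: ((), _f(112), Tier.negative),
}

_BASES = "ACGT"


def generate_case(scenario: Scenario) -> tuple[CaseInput, ScenarioTruth]:
    """Generate a deterministic synthetic case with its truth record.

    Background variants land in random panel genes with population
    frequencies above the filtering thresholds, or — when a frequency draw
    falls inside the survivable range — with a benign (synonymous)
    consequence, so that by construction only the spiked causal signal
    survives the pipeline.
    """
    panel = scenario.panel or load_canonical_panel()
    ontology = load_ontology(mini_ontology_path())
    db = known_pathogenic_db()
    mode_index = list(ScenarioMode).index(scenario.mode)
    rng = np.random.default_rng([scenario.seed % (2**31), mode_index])

    spikes, findings, truth_tier = _MODE_SPIKES[scenario.mode]
    reserved = {vd.key(panel) for vd in spikes} | set(db.records)
    symbols = panel.symbols()
    background: list[VariantDef] = []
    while len(background) < scenario.n_background_variants:
        gene = symbols[int(rng.integers(len(symbols)))]
        chrom, base = gene_locus(panel, gene)
        offset = int(rng.integers(1, 50_000))
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        if ref == alt:
            continue
        af = float(np.exp(rng.uniform(np.log(1e-4), np.log(0.5))))
        u = float(rng.random())
        cons = "missense" if u < 0.40 else "synonymous" if u < 0.70 \
            else "splice_region" if u < 0.80 else "other"
        if af <= 5e-3:
            cons = "synonymous"  # survivable frequency: keep it benign
        vd = VariantDef(
            gene, offset, ref, alt, cons,
            hgvs_c=f"c.{offset}{ref}>{alt}",
            predictors=(("polyphen", round(float(rng.random()), 3)),)
            if cons == "missense" else (),
            dist_to_exon=int(rng.integers(5, 500)),
            frequencies=(("intl_exac", af),),
        )
        if vd.key(panel) in reserved:
            continue
        reserved.add(vd.key(panel))
        background.append(vd)

    all_defs = tuple(spikes) + tuple(sorted(background, key=lambda v: v.key(panel)))
    cd = CaseDef(
        case_id=f"synthetic_{scenario.mode.value}_{scenario.seed}",
        findings=findings,
        variants=all_defs,
    )
    case = _case_input(cd, panel, ontology, db)
    case.notes["_defs"] = all_defs
    truth = ScenarioTruth(
        tier=truth_tier,
        causal_keys=frozenset(vd.key(panel) for vd in spikes),
        causal_gene=spikes[0].gene if spikes else None,
    )
    return case, truth


# ---------------------------------------------------------------------------
# Materialization to ordinary pipeline input files
# ---------------------------------------------------------------------------

_VCF_GT = {
    Zygosity.hom_ref: "0/0",
    Zygosity.het: "0/1",
    Zygosity.hom_alt: "1/1",
    Zygosity.missing: "./.",
}


def _write_case_vcf(path: Path, defs: tuple[VariantDef, ...], panel: GenePanel) -> list[str]:
    """Write one case's calls as a plain multi-sample VCF; returns samples."""
    samples = ["PROBAND"]
    if any(vd.maternal is not None for vd in defs):
        samples.append("MOTHER")
    if any(vd.paternal is not None for vd in defs):
        samples.append("FATHER")
    records = []
    for vd in defs:
        chrom, pos, ref, alt = vd.key(panel)
        gts = {"PROBAND": _VCF_GT[vd.zygosity]}
        if vd.maternal is not None:
            gts["MOTHER"] = "0/1" if vd.maternal else "0/0"
        elif "MOTHER" in samples:
            gts["MOTHER"] = "./."
        if vd.paternal is not None:
            gts["FATHER"] = "0/1" if vd.paternal else "0/0"
        elif "FATHER" in samples:
            gts["FATHER"] = "./."
        records.append((chrom, pos, ref, alt, gts))
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    contigs = sorted({r[0] for r in records})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            cols = [chrom, str(pos), ".", ref, alt, "50", "PASS", ".", "GT"]
            cols += [gts[s] for s in samples]
            fh.write("\t".join(cols) + "\n")
    return samples


def _write_sidecar(path: Path, defs: tuple[VariantDef, ...], panel: GenePanel) -> None:
    rows = []
    for vd in defs:
        chrom, pos, ref, alt = vd.key(panel)
        preds = ";".join(f"{k}={v:g}" for k, v in vd.predictors) or "."
        dist = "." if vd.dist_to_exon is None else str(vd.dist_to_exon)
        rows.append((chrom, pos, ref, alt, vd.gene, vd.consequence, vd.hgvs_c or ".",
                     vd.hgvs_p or ".", preds, "1" if vd.splice_pred else "0", dist))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tconsequence\thgvs_c\thgvs_p\tpredictors\tsplice_pred\tdist_to_exon\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def _write_frequency_tables(out_dir: Path, defs: list[VariantDef], panel: GenePanel) -> dict[str, Path]:
    by_source: dict[str, dict[VariantKey, float]] = {"local": {}, "intl_exac": {}}
    for vd in defs:
        for source, af in vd.frequencies:
            by_source.setdefault(source, {})[vd.key(panel)] = af
    paths = {}
    for source, table in sorted(by_source.items()):
        p = out_dir / f"freq_{source}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tref\talt\taf\n")
            for (chrom, pos, ref, alt), af in sorted(table.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af:g}\n")
        paths[source] = p
    return paths


def _write_known_db(path: Path) -> None:
    db = known_pathogenic_db()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#build={db.build}\n")
        fh.write("chrom\tpos\tref\talt\tgene\thgvs_c\thgvs_p\tcitation\tdbsnp\n")
        for (chrom, pos, ref, alt), rec in sorted(db.records.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{rec.gene}\t{rec.hgvs_c}\t"
                     f"{rec.hgvs_p}\t{rec.citation}\t{rec.dbsnp or '.'}\n")


def materialize_cohort(out_dir: Path | str) -> Path:
    """Write the full 14-case cohort as ordinary pipeline input files.

    Produces per-case VCF + annotation sidecar, the shared panel/ontology/
    known-db/frequency files, and a manifest TSV consumable by the cohort
    runner. Returns the manifest path. Output is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_canonical_panel()
    defs = table1_case_defs()

    shutil.copy(canonical_panel_path(), out / "panel_758_synthetic.tsv")
    shutil.copy(mini_ontology_path(), out / "mini_ontology.obo")
    _write_known_db(out / "known_pathogenic.tsv")
    all_vdefs = [vd for cd in defs for vd in cd.variants]
    _write_frequency_tables(out, all_vdefs, panel)

    manifest = out / "table1_manifest.tsv"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("#panel=panel_758_synthetic.tsv\n")
        fh.write("#obo=mini_ontology.obo\n")
        fh.write("#known_db=known_pathogenic.tsv\n")
        fh.write("#freq=local=freq_local.tsv;intl_exac=freq_intl_exac.tsv\n")
        fh.write("case_id\tvcf\tsidecar\tfindings\tproband\tmother\tfather\tsex\t"
                 "family_history\tsegregation_confirmed\ttwin\n")
        for cd in defs:
            vcf_path = out / f"{cd.case_id}.vcf"
            sidecar_path = out / f"{cd.case_id}.sidecar.tsv"
            samples = _write_case_vcf(vcf_path, cd.variants, panel)
            _write_sidecar(sidecar_path, cd.variants, panel)
            confirmed = ";".join(
                "{}:{}:{}:{}".format(*vd.key(panel))
                for vd in cd.variants if vd.segregation_confirmed
            ) or "."
            fh.write("\t".join([
                cd.case_id,
                vcf_path.name,
                sidecar_path.name,
                ";".join(cd.findings),
                "PROBAND",
                "MOTHER" if "MOTHER" in samples else ".",
                "FATHER" if "FATHER" in samples else ".",
                cd.fetal_sex.value,
                "1" if cd.family_history else "0",
                confirmed,
                "1" if cd.notes.get("twin_pregnancy") else "0",
            ]) + "\n")
    return manifest


def materialize_scenario(scenario: Scenario, out_dir: Path | str) -> tuple[Path, Path]:
    """Write one generated scenario's VCF + sidecar (+ frequency tables).

    Byte-identical for identical scenarios; returns (vcf, sidecar) paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = scenario.panel or load_canonical_panel()
    case, _truth = generate_case(scenario)
    defs: tuple[VariantDef, ...] = case.notes["_defs"]  # type: ignore[assignment]
    vcf = out / f"{case.case_id}.vcf"
    sidecar = out / f"{case.case_id}.sidecar.tsv"
    _write_case_vcf(vcf, defs, panel)
    _write_sidecar(sidecar, defs, panel)
    _write_frequency_tables(out, list(defs), panel)
    _write_known_db(out / "known_pathogenic.tsv")
    return vcf, sidecar
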