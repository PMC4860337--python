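"""VCF ingestion, sidecar joining, panel restriction, consequence mapping."""

import pytest

from fetalis.panel_registry import KnownPathogenicDB
from fetalis.variant_model import (
    AnnotatedVariant,
    Consequence,
    Variant,
    VariantAnnotation,
    VcfError,
    Zygosity,
    attach_annotations,
    classify_consequence,
    load_sidecar,
    normalize_hemizygous,
    read_vcf,
    restrict_to_panel,
)

FIXTURE_VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=X>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPROBAND\tMOTHER
1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30\t0/0:22
1\t200\t.\tCTT\tC\t50\tPASS\t.\tGT:DP\t1/1:28\t0/1:25
1\t300\t.\tG\tA\t50\tPASS\t.\tGT:DP\t0/0:30\t0/0:30
1\t400\t.\tA\tG,T\t50\tPASS\t.\tGT:DP\t1/2:31\t0/1:29
X\t500\t.\tT\tC\t50\tPASS\t.\tGT:DP\t0/1:20\t0/1:21
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    p = tmp_path / "fix.vcf"
    p.write_text(FIXTURE_VCF)
    return p


def test_read_vcf_zygosity_truth_table(fixture_vcf):
    variants = read_vcf(fixture_vcf, ["PROBAND", "MOTHER"])
    by_key = {v.key: v for v in variants}
    # 0/0-for-all record at 1:300 dropped; 1:400 decomposes into two
    assert len(variants) == 5
    assert by_key[("1", 100, "A", "G")].genotypes == {
        "PROBAND": Zygosity.het, "MOTHER": Zygosity.hom_ref,
    }
    assert by_key[("1", 200, "CTT", "C")].genotypes["PROBAND"] == Zygosity.hom_alt
    assert by_key[("1", 100, "A", "G")].depth == {"PROBAND": 30, "MOTHER": 22}


def test_multiallelic_het_decomposes_to_two_hets(fixture_vcf):
    variants = read_vcf(fixture_vcf, ["PROBAND"])
    alts = {v.key: v.genotypes["PROBAND"] for v in variants if v.pos == 400}
    assert alts == {
        ("1", 400, "A", "G"): Zygosity.het,
        ("1", 400, "A", "T"): Zygosity.het,
    }


def test_read_vcf_missing_sample_lists_available(fixture_vcf):
    with pytest.raises(VcfError, match="PROBAND"):
        read_vcf(fixture_vcf, ["FETUS"])


def test_hemizygous_normalization_male_x(fixture_vcf):
    variants = read_vcf(fixture_vcf, ["PROBAND"])
    normalize_hemizygous(variants, "PROBAND", "male")
    x = [v for v in variants if v.chrom == "X"][0]
    assert x.genotypes["PROBAND"] == Zygosity.hom_alt and x.hemizygous
    autosomal = [v for v in variants if v.key == ("1", 100, "A", "G")][0]
    assert autosomal.genotypes["PROBAND"] == Zygosity.het


# --- consequence normalization ---------------------------------------------


@pytest.mark.parametrize(
    "cons, dist, expected",
    [
        (Consequence.nonsense, 40, Consequence.nonsense),
        (Consequence.missense, 0, Consequence.missense),  # exonic boundary base
        (Consequence.splice_region, -2, Consequence.canonical_splice),
        (Consequence.other, -1, Consequence.canonical_splice),
        (Consequence.splice_region, -3, Consequence.splice_region),
        (Consequence.missense, None, Consequence.missense),
    ],
)
def test_classify_consequence_splice_rule(cons, dist, expected):
    ann = VariantAnnotation("G", cons, distance_to_exon_boundary=dist)
    assert classify_consequence(ann) == expected


# --- sidecar joining -------------------------------------------------------

SIDECAR = """chrom\tpos\tref\talt\tgene\tconsequence\thgvs_c\thgvs_p\tpredictors\tsplice_pred\tdist_to_exon
1\t100\tA\tG\tEVC2\tmissense_variant\tc.1A>G\tp.X\tpolyphen=0.8;sift_inv=0.6\t0\t30
1\t200\tCTT\tC\tNEB\tframeshift_variant\tc.2del\tp.Y\t.\t0\t10
1\t400\tA\tG\tCOL3A1\tstop_gained\tc.3A>G\tp.Z\t.\t0\t.
1\t400\tA\tT\tCOL3A1\tweird_label\tc.4A>T\tp.W\t.\t0\t.
"""


@pytest.fixture
def joined(tmp_path, fixture_vcf):
    side = tmp_path / "side.tsv"
    side.write_text(SIDECAR)
    variants = read_vcf(fixture_vcf, ["PROBAND"])
    db = KnownPathogenicDB({})
    freq = {"local": {}, "intl_exac": {("1", 100, "A", "G"): 1.647e-05}}
    return attach_annotations(variants, side, db, freq)


def test_attach_annotations_joins_and_audits(joined):
    annotated, audit = joined
    by_key = {a.key: a for a in annotated}
    a100 = by_key[("1", 100, "A", "G")]
    assert a100.gene == "EVC2"
    assert a100.annotation.predictor_scores == {"polyphen": 0.8, "sift_inv": 0.6}
    assert a100.frequencies == {"intl_exac": 1.647e-05}
    assert a100.freq_missing_sources == {"local"}
    # chrX record has no sidecar row -> audited, not silently dropped
    assert ("X", 500, "T", "C") in audit.unannotated
    # unrecognized consequence string maps to 'other'
    assert by_key[("1", 400, "A", "T")].annotation.consequence == Consequence.other


def test_duplicate_sidecar_key_rejected(tmp_path):
    side = tmp_path / "dup.tsv"
    side.write_text(SIDECAR + "1\t100\tA\tG\tEVC2\tmissense\tc.1A>G\tp.X\t.\t0\t30\n")
    with pytest.raises(VcfError, match="duplicate sidecar key"):
        load_sidecar(side)


# --- panel restriction -----------------------------------------------------


def _annotated(gene: str, pos: int) -> AnnotatedVariant:
    return AnnotatedVariant(
        Variant("1", pos, "A", "G", {"PROBAND": Zygosity.het}),
        VariantAnnotation(gene, Consequence.missense),
    )


def test_restrict_to_panel_filters_and_is_idempotent(demo_panel):
    variants = [_annotated(g, i) for i, g in enumerate(
        ["EVC2", "BRCA1", "NEB", "TP53", "OFFPANEL1", "ZIC1", "MYC", "PTPN11",
         "NOTCH9X", "KRASX"], start=1)]
    kept = restrict_to_panel(variants, demo_panel)
    assert [v.gene for v in kept] == ["EVC2", "NEB", "ZIC1", "PTPN11"]
    assert restrict_to_panel(kept, demo_panel) == kept
    assert restrict_to_panel([], demo_panel) == []
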