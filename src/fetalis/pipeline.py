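"""Single-case pipeline driver and bit-stable report writers.

Stage order: read VCF -> join annotation sidecar -> restrict to the panel
universe -> phenotype-prioritize genes -> local-frequency gate ->
international-frequency gate -> classify -> case-level evaluation. The
filter trace records the variant count entering and leaving every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .case_engine import (
    CaseConfig,
    CaseInput,
    CaseResult,
    ParentalGenotype,
    Sex,
    evaluate_case,
)
from .classifier import ClassifierConfig, VariantAssessment
from .frequency_filter import FrequencyPolicy
from .panel_registry import (
    VariantKey,
    load_known_pathogenic,
    load_panel,
    validate_panel_terms,
)
from .phenotype_prioritizer import FindingSet, compute_ic, load_ontology
from .variant_model import (
    Zygosity,
    attach_annotations,
    load_frequency_table,
    normalize_hemizygous,
    read_vcf,
    restrict_to_panel,
)

log = logging.getLogger("fetalis.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class PipelineConfig:
    vcf: Path
    sidecar: Path
    panel: Path
    ontology: Path
    known_db: Path
    freq_sources: dict[str, Path]
    findings: list[str]
    case_id: str = "case"
    proband: str = "PROBAND"
    mother: Optional[str] = None
    father: Optional[str] = None
    fetal_sex: str = "unknown"
    family_history: bool = False
    segregation_confirmed: list[str] = field(default_factory=list)  # chrom:pos:ref:alt
    max_af_dominant: float = 5e-4
    max_af_recessive: float = 5e-3
    ema_threshold: float = 70.0
    inframe_indels_obligatory: bool = False
    inherited_dominant_downgrade: bool = True
    min_gene_score: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.findings) <= 3:
            raise ValueError("1-3 finding terms required")
        for p in [self.vcf, self.sidecar, self.panel, self.ontology, self.known_db,
                  *self.freq_sources.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        base = Path(path).parent
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

        def _p(key: str) -> Path:
            return base / raw[key]

        return cls(
            vcf=_p("vcf"),
            sidecar=_p("sidecar"),
            panel=_p("panel"),
            ontology=_p("ontology"),
            known_db=_p("known_db"),
            freq_sources={k: base / v for k, v in raw["freq_sources"].items()},
            findings=list(raw["findings"]),
            **{k: raw[k] for k in (
                "case_id", "proband", "mother", "father", "fetal_sex",
                "family_history", "segregation_confirmed", "max_af_dominant",
                "max_af_recessive", "ema_threshold", "inframe_indels_obligatory",
                "inherited_dominant_downgrade", "min_gene_score", "seed",
            ) if k in raw},
        )

    def case_config(self) -> CaseConfig:
        return CaseConfig(
            frequency=FrequencyPolicy(self.max_af_dominant, self.max_af_recessive),
            classifier=ClassifierConfig(self.ema_threshold, self.inframe_indels_obligatory),
            min_gene_score=self.min_gene_score,
            inherited_dominant_downgrade=self.inherited_dominant_downgrade,
        )


def _parse_key(s: str) -> VariantKey:
    chrom, pos, ref, alt = s.split(":")
    return (chrom, int(pos), ref, alt)


def run_pipeline(config: PipelineConfig) -> CaseResult:
    """Execute the full single-case pipeline; returns the case result.

    An empty prioritized gene set yields a negative result with an
    explanatory note, not an error. Stage failures raise
    :class:`PipelineError` carrying the stage name.
    """
    try:
        panel = load_panel(config.panel)
        ontology = load_ontology(config.ontology)
        validate_panel_terms(panel, ontology)
        known_db = load_known_pathogenic(config.known_db)
        freq_tables = {s: load_frequency_table(p) for s, p in config.freq_sources.items()}
        icmap = compute_ic(ontology, panel)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("load_resources", str(e)) from e

    samples = [config.proband]
    if config.mother:
        samples.append(config.mother)
    if config.father:
        samples.append(config.father)
    try:
        variants = read_vcf(config.vcf, samples)
        normalize_hemizygous(variants, config.proband, config.fetal_sex)
    except Exception as e:
        raise PipelineError("read_vcf", str(e)) from e

    try:
        annotated, attach_audit = attach_annotations(
            variants, config.sidecar, known_db, freq_tables
        )
        restricted = restrict_to_panel(annotated, panel)
    except Exception as e:
        raise PipelineError("annotate", str(e)) from e

    parental: dict[VariantKey, ParentalGenotype] = {}
    for av in restricted:
        gts = av.variant.genotypes

        def _carrier(sample: Optional[str]) -> Optional[bool]:
            if not sample or sample not in gts:
                return None
            z = gts[sample]
            if z == Zygosity.missing:
                return None
            return z in (Zygosity.het, Zygosity.hom_alt)

        m, p = _carrier(config.mother), _carrier(config.father)
        if m is not None or p is not None:
            parental[av.key] = ParentalGenotype(m, p)

    # carry proband zygosity under the canonical sample key expected downstream
    for av in restricted:
        z = av.variant.genotypes.get(config.proband, Zygosity.missing)
        av.variant.genotypes["PROBAND"] = z

    case = CaseInput(
        case_id=config.case_id,
        findings=FindingSet.from_terms(config.findings, ontology),
        variants=restricted,
        parental_genotypes=parental,
        fetal_sex=Sex(config.fetal_sex),
        family_history_flag=config.family_history,
        segregation_confirmed=frozenset(_parse_key(s) for s in config.segregation_confirmed),
    )
    trace = {
        "vcf_records": len(variants),
        "annotated": len(annotated),
        "panel_restricted": len(restricted),
    }
    try:
        return evaluate_case(case, panel, ontology, icmap, config.case_config(), trace)
    except Exception as e:
        raise PipelineError("evaluate_case", str(e)) from e


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def _assessment_dict(a: VariantAssessment) -> dict:
    chrom, pos, ref, alt = a.variant.key
    return {
        "gene": a.gene,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "hgvs_c": a.variant.annotation.hgvs_c,
        "hgvs_p": a.variant.annotation.hgvs_p,
        "consequence": a.variant.annotation.consequence.value,
        "class": a.variant_class.label,
        "ema_score": a.ema_score,
        "known_pathogenic": a.variant.known_pathogenic,
        "frequencies": dict(sorted(a.variant.frequencies.items())),
        "absent_from_sources": sorted(a.variant.freq_missing_sources),
        "rationale": list(a.rationale),
    }


def result_dict(result: CaseResult) -> dict:
    return {
        "case_id": result.case_id,
        "tier": result.tier.value,
        "diagnoses": [
            {
                "gene": d.gene,
                "disorder": d.disorder,
                "inheritance": d.inheritance_model.value,
                "segregation": d.segregation,
                "tier": d.tier.value,
                "variants": [_assessment_dict(a) for a in d.assessments],
            }
            for d in result.diagnoses
        ],
        "candidates_for_review": [_assessment_dict(a) for a in result.candidates_for_review],
        "filter_trace": dict(result.filter_trace),
        "gene_scores": {g: round(s, 6) for g, s in sorted(result.gene_scores.items())},
        "warnings": list(result.warnings),
    }


def write_report(result: CaseResult, out_dir: Path | str,
                 formats: tuple[str, ...] = ("json", "tsv")) -> list[Path]:
    """Write the machine (JSON) and review-list (TSV) reports.

    JSON keys are sorted and floats rounded, so identical results produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out / f"{result.case_id}.report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(result_dict(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    if "tsv" in formats:
        p = out / f"{result.case_id}.review.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("rank\tgene\thgvs_c\thgvs_p\tclass\tema_score\trationale\n")
            for rank, a in enumerate(result.candidates_for_review, start=1):
                score = "" if a.ema_score is None else f"{a.ema_score:g}"
                fh.write("\t".join([
                    str(rank), a.gene, a.variant.annotation.hgvs_c,
                    a.variant.annotation.hgvs_p, a.variant_class.label,
                    score, " | ".join(a.rationale),
                ]) + "\n")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Cohort runner
# ---------------------------------------------------------------------------


def run_cohort(manifest: Path | str, out_dir: Optional[Path | str] = None) -> dict[str, CaseResult]:
    """Run every case listed in a cohort manifest; optionally write reports.

    The manifest is a TSV with ``#key=value`` comment headers naming the
    shared panel/ontology/known-db/frequency files (paths relative to the
    manifest directory) and one row per case.
    """
    manifest = Path(manifest)
    base = manifest.parent
    shared: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: Optional[list[str]] = None
    with open(manifest, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                shared[key] = val
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append(dict(zip(header, fields)))
    freq_sources = {}
    for part in shared.get("freq", "").split(";"):
        if part:
            source, _, rel = part.partition("=")
            freq_sources[source] = base / rel

    results: dict[str, CaseResult] = {}
    for row in rows:
        cfg = PipelineConfig(
            vcf=base / row["vcf"],
            sidecar=base / row["sidecar"],
            panel=base / shared["panel"],
            ontology=base / shared["obo"],
            known_db=base / shared["known_db"],
            freq_sources=freq_sources,
            findings=row["findings"].split(";"),
            case_id=row["case_id"],
            proband=row.get("proband", "PROBAND"),
            mother=None if row.get("mother", ".") == "." else row["mother"],
            father=None if row.get("father", ".") == "." else row["father"],
            fetal_sex=row.get("sex", "unknown"),
            family_history=row.get("family_history", "0") == "1",
            segregation_confirmed=[
                s for s in row.get("segregation_confirmed", ".").split(";") if s and s != "."
            ],
        )
        result = run_pipeline(cfg)
        results[row["case_id"]] = result
        if out_dir is not None:
            write_report(result, out_dir)
    if out_dir is not None:
        summary = Path(out_dir) / "cohort_summary.tsv"
        with open(summary, "w", encoding="utf-8") as fh:
            fh.write("case_id\ttier\tn_diagnoses\tn_candidates\n")
            for cid, r in results.items():
                fh.write(f"{cid}\t{r.tier.value}\t{len(r.diagnoses)}\t"
                         f"{len(r.candidates_for_review)}\n")
    return results
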