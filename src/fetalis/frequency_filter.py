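"""Staged population allele-frequency gates.

Variants are checked first against the local population database, then
against the international sources (1000 Genomes / EVS / ExAC analogs), each
stage applying an inheritance-aware threshold: dominant-acting genes use a
stricter cut-off than recessive ones (carriers of recessive alleles
circulate at appreciable frequency). Dual-mode (AD_AR) and X-linked genes
use the recessive threshold. A documented known-pathogenic allele is never
frequency-excluded.

The default cut-offs (5e-4 dominant, 5e-3 recessive) are calibrated so that
bona fide rare pathogenic alleles (observed frequencies in the 1e-5..1e-4
range, or absent from all sources) survive while common population
polymorphisms do not; both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .panel_registry import Inheritance
from .variant_model import AnnotatedVariant

log = logging.getLogger("fetalis.frequency")

LOCAL_SOURCE = "local"
STAGE_ORDER = ("local", "international")


@dataclass
class FrequencyPolicy:
    max_af_dominant: float = 5e-4
    max_af_recessive: float = 5e-3

    def __post_init__(self) -> None:
        for t in (self.max_af_dominant, self.max_af_recessive):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"frequency threshold {t} outside [0,1]")
        if self.max_af_dominant > self.max_af_recessive:
            raise ValueError("dominant threshold must not exceed the recessive threshold")

    def threshold_for(self, inheritance: Inheritance) -> float:
        if inheritance == Inheritance.AD:
            return self.max_af_dominant
        return self.max_af_recessive


@dataclass
class FrequencyAudit:
    """Per-stage discard bookkeeping, ordered local -> international."""

    stage_discards: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STAGE_ORDER})
    discarded: list[AnnotatedVariant] = field(default_factory=list)
    exempted_known: int = 0


def _fails_stage(v: AnnotatedVariant, stage: str, threshold: float) -> bool:
    for source, af in v.frequencies.items():
        is_local = source == LOCAL_SOURCE
        if (stage == "local") == is_local and af > threshold:
            return True
    return False


def apply_frequency_filter(
    variants: list[AnnotatedVariant],
    policy: FrequencyPolicy,
    inheritance: dict[str, Inheritance],
) -> tuple[list[AnnotatedVariant], FrequencyAudit]:
    """Apply the local then international frequency gates.

    A variant survives iff its frequency in every configured source is at or
    below the threshold for its gene's inheritance mode; frequencies absent
    from a source count as 0.0 (novel alleles survive). The stages commute
    set-wise; the fixed order only shapes the audit counts.
    """
    audit = FrequencyAudit()
    survivors = list(variants)
    for stage in STAGE_ORDER:
        kept: list[AnnotatedVariant] = []
        for v in survivors:
            if v.known_pathogenic:
                audit.exempted_known += _fails_stage(
                    v, stage, policy.threshold_for(inheritance.get(v.gene, Inheritance.AR))
                )
                kept.append(v)
                continue
            thr = policy.threshold_for(inheritance.get(v.gene, Inheritance.AR))
            if _fails_stage(v, stage, thr):
                audit.stage_discards[stage] += 1
                audit.discarded.append(v)
            else:
                kept.append(v)
        log.info(
            "frequency stage %s: %d -> %d variants", stage, len(survivors), len(kept)
        )
        survivors = kept
    return survivors, audit
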