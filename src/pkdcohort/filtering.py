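"""Variant prioritization: a deterministic, auditable pass over records.

A variant survives when it is exonic or splicing, non-synonymous (or an
indel), rare (population allele frequency not over 1%), and passes three
quality gates: variant quality >= 20, genotype quality >= 30 and mean
mapping quality strictly > 30.  Every dropped record carries the full list
of reasons, not just the first one, so a filter run is auditable.

A dbSNP identifier by itself never excludes a variant: absence of
frequency evidence is treated as rare, since novelty is not evidence of
commonness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .models import Region, VariantRecord

__all__ = ["FilterReason", "FilterDecision", "FilterThresholds", "prioritize_variants"]


class FilterReason(str, Enum):
    NOT_EXONIC_SPLICING = "not_exonic_splicing"
    COMMON_AF = "common_af"
    LOW_QUAL = "low_qual"
    LOW_GQ = "low_gq"
    LOW_MQ = "low_mq"
    SYNONYMOUS = "synonymous"


@dataclass(frozen=True)
class FilterThresholds:
    """Boundary semantics exactly as stated: AF strictly > af_max dropped;
    qual < qual_min dropped; GQ < gq_min dropped; MQ <= mq_min dropped."""

    af_max: float = 0.01
    qual_min: float = 20.0
    gq_min: float = 30.0
    mq_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("af_max", "qual_min", "gq_min", "mq_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")


@dataclass
class FilterDecision:
    variant_key: str
    kept: bool
    reasons: list[FilterReason] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kept != (not self.reasons):
            raise ValueError("kept must be equivalent to an empty reason list")


def _decide(rec: VariantRecord, t: FilterThresholds) -> list[FilterReason]:
    reasons: list[FilterReason] = []
    if rec.region not in (Region.EXONIC, Region.SPLICING):
        reasons.append(FilterReason.NOT_EXONIC_SPLICING)
    if rec.synonymous and not rec.is_indel:
        reasons.append(FilterReason.SYNONYMOUS)
    # absent pop_af is treated as rare: novelty is not exclusionary
    if rec.pop_af is not None and rec.pop_af > t.af_max:
        reasons.append(FilterReason.COMMON_AF)
    if rec.qual is not None and rec.qual < t.qual_min:
        reasons.append(FilterReason.LOW_QUAL)
    if rec.genotype_quality is not None and rec.genotype_quality < t.gq_min:
        reasons.append(FilterReason.LOW_GQ)
    if rec.mapping_quality is not None and rec.mapping_quality <= t.mq_min:
        reasons.append(FilterReason.LOW_MQ)
    return reasons


def prioritize_variants(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantRecord], list[FilterDecision]]:
    """Apply all prioritization rules; return (kept records, full audit).

    Output order preserves input order; the audit has exactly one entry per
    input record, with the exhaustive reason list for dropped records.
    """
    kept: list[VariantRecord] = []
    audit: list[FilterDecision] = []
    for rec in records:
        reasons = _decide(rec, thresholds)
        if not reasons:
            kept.append(rec)
        audit.append(FilterDecision(variant_key=rec.key, kept=not reasons, reasons=reasons))
    return kept, audit
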