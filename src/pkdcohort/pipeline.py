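"""End-to-end orchestration of the variant-interpretation workflow.

Per family: prioritize the sequencing-detected variants, classify the
survivors against the transcript models, look each up in the known-variant
database, grade, and -- for novel LP variants with informative relatives --
re-grade with familial segregation evidence.  Families left without a
mutation fall through the rescue ladder: exon-1 Sanger results first, then
the depth-ratio CNV screen reconciled with MLPA.  The result carries each
family's representative mutation, detection stage and genotype group,
ready for the cohort statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .classification import (
    annotate_consequence,
    assign_grade,
    assign_genotype_group,
    insilico_verdict,
)
from .cnv import CNVCall, CNVThresholds, call_cnv, normalize_depth, reconcile_mlpa
from .filtering import FilterDecision, FilterThresholds, prioritize_variants
from .models import (
    CohortBundle,
    Family,
    Gene,
    GenotypeGroup,
    Grade,
    KnownStatus,
    SegregationStatus,
    VariantClass,
    VariantRecord,
)
from .segregation import SegregationResult, evaluate_segregation
from .stats import (
    ClassGradeTable,
    DetectionSummary,
    detection_summary,
    novelty_rate,
    representative_variant,
    tabulate_class_grade,
)

__all__ = ["FamilyResult", "PipelineResult", "run_pipeline", "cnv_call_to_variant"]


@dataclass
class FamilyResult:
    family_id: str
    stage: str  # tes | sanger_exon1 | mlpa | none
    representative: Optional[VariantRecord]
    genotype_group: GenotypeGroup
    graded: list[VariantRecord] = field(default_factory=list)
    segregation: Optional[SegregationResult] = None
    audit: list[FilterDecision] = field(default_factory=list)


@dataclass
class PipelineResult:
    families: list[FamilyResult]
    detection: DetectionSummary
    table: ClassGradeTable
    n_novel: Optional[int] = None
    novelty_pct: Optional[float] = None
    cnv_calls: list[CNVCall] = field(default_factory=list)
    cnv_report: dict = field(default_factory=dict)


def cnv_call_to_variant(call: CNVCall) -> VariantRecord:
    """Export a CNV call as a gradeable large-deletion/duplication record."""
    chrom = "16" if call.gene is Gene.PKD1 else "4"
    alt = "<DEL>" if call.call.value == "deletion" else "<DUP>"
    rec = VariantRecord(
        chrom=chrom,
        pos=1,
        ref="N",
        alt=alt,
        gene=call.gene,
        exon=call.exon_start,
        hgvs_c=f"exon{call.exon_start}_{call.exon_end}{alt[1:4].lower()}",
        vclass=VariantClass.LARGE_DEL_DUP,
    )
    return rec


def _grade_record(
    rec: VariantRecord,
    bundle: CohortBundle,
    segregation: SegregationStatus = SegregationStatus.UNTESTED,
) -> None:
    if rec.known_status is KnownStatus.NONE and bundle.known_db is not None:
        rec.known_status = bundle.known_db.lookup(rec.key)
    rec.grade = assign_grade(
        rec.vclass, rec.known_status, insilico_verdict(rec), segregation
    )


def run_pipeline(
    bundle: CohortBundle,
    thresholds: FilterThresholds = FilterThresholds(),
    cnv_thresholds: CNVThresholds = CNVThresholds(),
    min_informative: int = 1,
    penetrance_age: float = 40.0,
) -> PipelineResult:
    """Run filtering, classification, grading, segregation re-grading and
    the rescue ladder over a cohort bundle; tabulate the outcome."""
    # depth screen once for the whole cohort
    cnv_by_sample: dict[str, list[CNVCall]] = {}
    cnv_calls: list[CNVCall] = []
    cnv_report: dict = {}
    if bundle.depth is not None and len(bundle.depth.sample_ids) >= 3:
        ratios = normalize_depth(bundle.depth)
        cnv_calls = call_cnv(ratios, cnv_thresholds)
        if bundle.mlpa is not None and len(bundle.mlpa):
            cnv_calls, cnv_report = reconcile_mlpa(cnv_calls, bundle.mlpa)
        for call in cnv_calls:
            cnv_by_sample.setdefault(call.sample_id, []).append(call)

    results: list[FamilyResult] = []
    variants_by_family: dict[str, list[VariantRecord]] = {}
    for fam in bundle.families:
        res = _process_family(
            fam, bundle, thresholds, cnv_by_sample, min_informative, penetrance_age
        )
        results.append(res)
        fam.detection_stage = res.stage
        fam.resolved_genotype = res.genotype_group
        variants_by_family[fam.family_id] = (
            [res.representative] if res.representative is not None else []
        )

    detection = detection_summary(
        res.stage if res.stage != "none" else "none" for res in results
    )
    table = tabulate_class_grade(variants_by_family)
    mutation_keys = [
        r.representative.key
        for r in results
        if r.representative is not None and r.representative.grade.is_mutation
    ]
    n_novel = pct = None
    if mutation_keys and bundle.known_db is not None:
        n_novel, pct = novelty_rate(mutation_keys, bundle.known_db)
    return PipelineResult(
        families=results,
        detection=detection,
        table=table,
        n_novel=n_novel,
        novelty_pct=pct,
        cnv_calls=cnv_calls,
        cnv_report=cnv_report,
    )


def _process_family(
    fam: Family,
    bundle: CohortBundle,
    thresholds: FilterThresholds,
    cnv_by_sample: dict[str, list[CNVCall]],
    min_informative: int,
    penetrance_age: float,
) -> FamilyResult:
    records = [bundle.variants[k] for k in fam.variants if k in bundle.variants]
    kept, audit = prioritize_variants(records, thresholds)

    graded: list[VariantRecord] = []
    for rec in kept:
        tx = bundle.transcripts.get(rec.gene.value)
        if tx is not None and rec.vclass is None:
            try:
                annotate_consequence(rec, tx)
            except ValueError:
                continue
        if rec.vclass is None:  # synonymous survivor or unclassifiable
            continue
        _grade_record(rec, bundle)
        graded.append(rec)

    segregation_result: Optional[SegregationResult] = None
    rep = representative_variant(
        [r for r in graded if r.grade is not None and r.grade.is_mutation]
        or [r for r in graded if r.grade is not None]
    )
    # novel LP variants undergo familial segregation analysis
    if (
        rep is not None
        and rep.grade is Grade.LP
        and rep.known_status is KnownStatus.NONE
    ):
        try:
            segregation_result = evaluate_segregation(
                fam,
                rep.key,
                min_informative=min_informative,
                penetrance_age=penetrance_age,
            )
            _grade_record(rep, bundle, segregation_result.status)
        except (KeyError, ValueError):
            pass
        if rep.grade is not None and not rep.grade.is_mutation:
            rep = representative_variant(
                [r for r in graded if r.grade is not None and r.grade.is_mutation]
            )

    if rep is not None and rep.grade.is_mutation:
        return FamilyResult(
            family_id=fam.family_id,
            stage="tes",
            representative=rep,
            genotype_group=assign_genotype_group(
                rep.gene, rep.vclass, rep.indel_aa_len, rep.grade
            ),
            graded=graded,
            segregation=segregation_result,
            audit=audit,
        )

    # rescue 1: exon-1 Sanger sequencing
    sanger_key = bundle.sanger_exon1.get(fam.family_id)
    if sanger_key is not None and sanger_key in bundle.variants:
        rec = bundle.variants[sanger_key]
        tx = bundle.transcripts.get(rec.gene.value)
        if tx is not None and rec.vclass is None:
            annotate_consequence(rec, tx)
        if rec.vclass is not None:
            _grade_record(rec, bundle)
            if rec.grade.is_mutation:
                return FamilyResult(
                    family_id=fam.family_id,
                    stage="sanger_exon1",
                    representative=rec,
                    genotype_group=assign_genotype_group(
                        rec.gene, rec.vclass, rec.indel_aa_len, rec.grade
                    ),
                    graded=graded + [rec],
                    segregation=segregation_result,
                    audit=audit,
                )

    # rescue 2: depth screen / MLPA for large rearrangements
    proband_sample = f"{fam.family_id}_P"
    calls = cnv_by_sample.get(proband_sample, [])
    depth_call = next((c for c in calls if c.source == "depth"), None)
    mlpa_call = next((c for c in calls if c.source == "mlpa"), None)
    chosen = depth_call or mlpa_call
    if chosen is not None:
        rec = cnv_call_to_variant(chosen)
        _grade_record(rec, bundle)
        return FamilyResult(
            family_id=fam.family_id,
            stage="tes" if chosen.source == "depth" else "mlpa",
            representative=rec,
            genotype_group=assign_genotype_group(
                rec.gene, rec.vclass, rec.indel_aa_len, rec.grade
            ),
            graded=graded + [rec],
            segregation=segregation_result,
            audit=audit,
        )

    return FamilyResult(
        family_id=fam.family_id,
        stage="none",
        representative=rep,
        genotype_group=GenotypeGroup.NM,
        graded=graded,
        segregation=segregation_result,
        audit=audit,
    )
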