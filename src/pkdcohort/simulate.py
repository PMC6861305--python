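"""Synthetic family-cohort generator.

Generates complete, statistically faithful cohorts -- annotated variants on
toy PKD1/PKD2 transcript models, pedigrees with Mendelian transmission,
per-exon depth matrices with injected exon-level deletions/duplications,
and clinical phenotypes drawn from the published regression structure --
so that every pipeline stage runs and can be scored against truth without
any external download.

Default parameters are the study conditions: genotype-group mix
59/3/19/19% among detected families plus a 101/524 no-mutation fraction,
class frequencies from the cohort tabulation, log10(htTKV) and eGFR
fixed-effect coefficients from the multilevel regression, and
genotype-specific ESRD median ages (63.5/72.7/68.8/72.9 y) realised
through a Weibull clock.  All randomness flows from the single mandatory
seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classification import CODON_TABLE, TranscriptModel
from .models import (
    Affection,
    Carrier,
    CohortBundle,
    DepthMatrix,
    Family,
    Gene,
    GenotypeGroup,
    Grade,
    KnownVariantDB,
    PedigreeIndividual,
    PolyPhenCall,
    Region,
    Sex,
    SubjectPhenotype,
    VariantClass,
    VariantRecord,
)

__all__ = [
    "GeneratorConfig",
    "build_toy_transcript",
    "generate_cohort",
    "generate_phenotypes",
    "generate_depth_matrix",
    "sample_esrd_ages",
    "write_bundle",
    "load_bundle",
]

_DETECTED_GROUPS = (
    GenotypeGroup.PKD1_PT,
    GenotypeGroup.PKD1_ID,
    GenotypeGroup.PKD1_NT,
    GenotypeGroup.PKD2,
)

_PKD1_TRUNCATING = (
    VariantClass.NONSENSE,
    VariantClass.FRAMESHIFT,
    VariantClass.TYPICAL_SPLICING,
    VariantClass.LARGE_DEL_DUP,
)
_PKD2_CLASSES = (
    VariantClass.NONSENSE,
    VariantClass.FRAMESHIFT,
    VariantClass.TYPICAL_SPLICING,
    VariantClass.LARGE_DEL_DUP,
    VariantClass.MISSENSE,
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, seeded and validated.

    Defaults encode the study conditions; distributional choices without a
    published value (typing probability, family structure, in-silico score
    distributions, depth model) are fixed once and documented in the
    methods note.
    """

    seed: int
    n_families: int = 524
    n_subjects_target: Optional[int] = None
    nm_fraction: float = 101 / 524
    genotype_group_probs: tuple[float, float, float, float] = (0.59, 0.03, 0.19, 0.19)
    # class mixes within gene, from the cohort class tabulation
    pkd1_truncating_class_probs: tuple[float, float, float, float] = (
        86 / 246,
        136 / 246,
        16 / 246,
        8 / 246,
    )
    pkd2_class_probs: tuple[float, float, float, float, float] = (
        39 / 75,
        11 / 75,
        8 / 75,
        5 / 75,
        12 / 75,
    )
    known_fraction: float = 97 / 331
    known_label_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)  # DP/HLP/LP
    decoy_rate: float = 2.0  # Poisson mean benign decoys per family
    # pedigree structure
    parent_prob: float = 0.55
    sibling_rate: float = 0.8
    typed_prob: float = 0.8
    penetrance_age: float = 40.0
    # demographics
    mean_age: float = 46.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 85.0
    male_prob: float = 0.48
    # phenotype models (fixed effects; reference group PKD1_PT)
    httkv_coefs: dict = field(
        default_factory=lambda: {
            "const": 2.378,
            "age": 0.012,
            "male": 0.102,
            "PKD1_ID": -0.033,
            "PKD1_NT": -0.153,
            "PKD2": -0.161,
        }
    )
    egfr_coefs: dict = field(
        default_factory=lambda: {
            "const": 148.405,
            "age": -1.840,
            "male": -6.535,
            "PKD1_ID": 2.668,
            "PKD1_NT": 7.278,
            "PKD2": 18.476,
        }
    )
    httkv_residual_sd: float = 0.2
    httkv_family_sd: float = 0.1
    egfr_residual_sd: float = 15.0
    egfr_family_sd: float = 8.0
    esrd_median_by_group: dict = field(
        default_factory=lambda: {
            "PKD1_PT": 63.5,
            "PKD1_ID": 72.7,
            "PKD1_NT": 68.8,
            "PKD2": 72.9,
            "NM": 72.9,
        }
    )
    weibull_shape: float = 6.0
    # in-silico score distributions conditional on pathogenicity
    damaging_sift_beta: tuple[float, float] = (0.5, 20.0)
    damaging_pp2_prob: float = 0.9
    damaging_gerp_mean: float = 5.5
    damaging_gerp_sd: float = 1.0
    benign_sift_beta: tuple[float, float] = (2.0, 2.0)
    benign_pp2_prob: float = 0.1
    benign_gerp_mean: float = 1.5
    benign_gerp_sd: float = 1.5
    score_missing_prob: float = 0.05
    # depth model
    depth_mean: float = 1000.0
    depth_nb_size: float = 200.0
    library_factor_sd: float = 0.2
    capture_factor_sd: float = 0.2
    cnv_max_span: int = 5
    large_del_depth_detectable_prob: float = 0.5
    exon1_tes_dropout: bool = True  # PKD1 exon-1 SNVs missed by capture (GC-rich)
    with_depth: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("genotype_group_probs", "pkd1_truncating_class_probs", "pkd2_class_probs", "known_label_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if not (0.0 <= self.nm_fraction <= 1.0):
            raise ValueError("nm_fraction must be in [0, 1]")
        if self.nm_fraction >= 1.0 and any(p > 0 for p in self.genotype_group_probs):
            raise ValueError(
                "impossible config: nm_fraction = 1 leaves no families for the "
                "nonzero genotype-group probabilities"
            )
        for name in (
            "httkv_residual_sd",
            "httkv_family_sd",
            "egfr_residual_sd",
            "egfr_family_sd",
            "library_factor_sd",
            "capture_factor_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Toy transcripts

_NON_STOP = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def build_toy_transcript(
    gene: Gene,
    rng: np.random.Generator,
    n_exons: Optional[int] = None,
    codons_per_exon: int = 12,
    intron_len: int = 60,
) -> TranscriptModel:
    """A fully coding toy transcript with codon-aligned exons.

    PKD1 gets 46 exons on chromosome 16, PKD2 15 exons on chromosome 4
    (matching the genes' real exon counts); sequences are random non-stop
    codons between an ATG and a terminal TAA.
    """
    gene = Gene(gene)
    if n_exons is None:
        n_exons = 46 if gene is Gene.PKD1 else 15
    chrom = "16" if gene is Gene.PKD1 else "4"
    n_codons = n_exons * codons_per_exon
    body = rng.choice(_NON_STOP, size=n_codons - 2)
    seq = "ATG" + "".join(body) + "TAA"
    exon_len = codons_per_exon * 3
    exons = []
    start = 1_000
    for _ in range(n_exons):
        exons.append((start, start + exon_len - 1))
        start += exon_len + intron_len
    return TranscriptModel(
        gene=gene,
        strand="+",
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
        sequence=seq,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# Variant synthesis against a transcript


def _snv_for_outcome(
    tx: TranscriptModel, rng: np.random.Generator, outcome: str
) -> tuple[int, str, str, int]:
    """Find (pos, ref, alt, exon) whose local codon change realises
    ``outcome`` in {nonsense, missense, synonymous}."""
    cds = tx.cds_sequence
    n = len(cds)
    for _ in range(2000):
        c = int(rng.integers(3, n - 3))  # spare the start and stop codons
        codon_idx, within = divmod(c, 3)
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        ref = cds[c]
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            mutated = codon[:within] + alt + codon[within + 1 :]
            aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutated]
            got = (
                "nonsense"
                if aa_alt == "*"
                else "synonymous" if aa_alt == aa_ref else "missense"
            )
            if got == outcome:
                pos = tx.genomic_pos(tx._cds_lo + c)
                return pos, ref, alt, tx.exon_number(pos)
    raise RuntimeError(f"could not synthesise a {outcome} SNV")


def _indel(
    tx: TranscriptModel, rng: np.random.Generator, length: int, insertion: bool
) -> tuple[int, str, str, int]:
    """VCF-style left-anchored indel confined to a single exon."""
    for _ in range(2000):
        exon_i = int(rng.integers(0, len(tx.exons)))
        s, e = tx.exons[exon_i]
        if e - s + 1 < length + 2:
            continue
        pos = int(rng.integers(s + 1, e - length))  # anchor inside the exon
        t = tx.tx_index(pos)
        if insertion:
            ref = tx.sequence[t]
            ins = "".join(rng.choice(list("ACGT"), size=length))
            return pos, ref, ref + ins, exon_i + 1
        ref = tx.sequence[t : t + length + 1]
        return pos, ref, ref[0], exon_i + 1
    raise RuntimeError("could not synthesise indel")


def _splice_snv(
    tx: TranscriptModel, rng: np.random.Generator
) -> tuple[int, str, str, int]:
    boundary = int(rng.integers(0, len(tx.exons) - 1))
    s, e = tx.exons[boundary]
    offset = int(rng.integers(1, 3))  # +1 or +2 donor position
    pos = e + offset
    return pos, "G", "A", boundary + 1


@dataclass
class _CausalSpec:
    record: Optional[VariantRecord]
    vclass: VariantClass
    cnv_span: Optional[tuple[int, int]] = None  # exon range for large events
    cnv_type: str = "deletion"
    via_sanger: bool = False
    depth_detectable: bool = True


def _sample_scores(
    rec: VariantRecord, cfg: GeneratorConfig, rng: np.random.Generator, damaging: bool
) -> None:
    a, b = cfg.damaging_sift_beta if damaging else cfg.benign_sift_beta
    pp2_prob = cfg.damaging_pp2_prob if damaging else cfg.benign_pp2_prob
    g_mean = cfg.damaging_gerp_mean if damaging else cfg.benign_gerp_mean
    g_sd = cfg.damaging_gerp_sd if damaging else cfg.benign_gerp_sd
    if rng.random() >= cfg.score_missing_prob:
        rec.sift = float(np.clip(rng.beta(a, b), 0.0, 1.0))
    if rng.random() >= cfg.score_missing_prob:
        rec.polyphen_call = (
            PolyPhenCall.DAMAGING if rng.random() < pp2_prob else PolyPhenCall.BENIGN
        )
    if rng.random() >= cfg.score_missing_prob:
        rec.gerp = float(rng.normal(g_mean, g_sd))


def _quality_fields(rec: VariantRecord, rng: np.random.Generator, good: bool = True) -> None:
    if good:
        rec.qual = float(np.clip(rng.normal(60, 10), 25, 99))
        rec.genotype_quality = float(np.clip(rng.normal(70, 12), 35, 99))
        rec.mapping_quality = float(np.clip(rng.normal(55, 5), 35, 60))
    else:
        rec.qual = float(rng.uniform(2, 18))
        rec.genotype_quality = float(rng.uniform(5, 28))
        rec.mapping_quality = float(rng.uniform(10, 29))


def _sample_causal(
    group: GenotypeGroup,
    txs: dict[Gene, TranscriptModel],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> _CausalSpec:
    if group is GenotypeGroup.PKD2:
        gene = Gene.PKD2
        vclass = _PKD2_CLASSES[
            rng.choice(len(_PKD2_CLASSES), p=cfg.pkd2_class_probs)
        ]
    else:
        gene = Gene.PKD1
        if group is GenotypeGroup.PKD1_PT:
            vclass = _PKD1_TRUNCATING[
                rng.choice(len(_PKD1_TRUNCATING), p=cfg.pkd1_truncating_class_probs)
            ]
        elif group is GenotypeGroup.PKD1_ID:
            vclass = VariantClass.INFRAME_INDEL
        else:
            vclass = VariantClass.MISSENSE
    tx = txs[gene]

    if vclass is VariantClass.LARGE_DEL_DUP:
        span_len = int(rng.integers(1, cfg.cnv_max_span + 1))
        start = int(rng.integers(1, len(tx.exons) - span_len + 2))
        cnv_type = "deletion" if rng.random() < 0.8 else "duplication"
        return _CausalSpec(
            record=None,
            vclass=vclass,
            cnv_span=(start, start + span_len - 1),
            cnv_type=cnv_type,
            depth_detectable=rng.random() < cfg.large_del_depth_detectable_prob,
        )

    if vclass is VariantClass.NONSENSE:
        pos, ref, alt, exon = _snv_for_outcome(tx, rng, "nonsense")
    elif vclass is VariantClass.MISSENSE:
        pos, ref, alt, exon = _snv_for_outcome(tx, rng, "missense")
    elif vclass is VariantClass.TYPICAL_SPLICING:
        pos, ref, alt, exon = _splice_snv(tx, rng)
    elif vclass is VariantClass.FRAMESHIFT:
        length = int(rng.integers(1, 3))
        pos, ref, alt, exon = _indel(tx, rng, length, insertion=bool(rng.integers(2)))
    else:  # small in-frame indel, < 5 aa for the ID group
        aa = int(rng.integers(1, 5))
        pos, ref, alt, exon = _indel(tx, rng, 3 * aa, insertion=bool(rng.integers(2)))

    rec = VariantRecord(
        chrom=tx.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        exon=exon,
        region=Region.SPLICING if vclass is VariantClass.TYPICAL_SPLICING else Region.EXONIC,
        pop_af=float(rng.uniform(0, 0.004)) if rng.random() < 0.3 else None,
    )
    _quality_fields(rec, rng, good=True)
    if vclass in (VariantClass.MISSENSE, VariantClass.INFRAME_INDEL):
        _sample_scores(rec, cfg, rng, damaging=True)
    via_sanger = (
        cfg.exon1_tes_dropout and gene is Gene.PKD1 and exon == 1
        and vclass is not VariantClass.TYPICAL_SPLICING
    )
    return _CausalSpec(record=rec, vclass=vclass, via_sanger=via_sanger)


def _sample_decoy(
    txs: dict[Gene, TranscriptModel], cfg: GeneratorConfig, rng: np.random.Generator
) -> VariantRecord:
    gene = Gene.PKD1 if rng.random() < 0.7 else Gene.PKD2
    tx = txs[gene]
    kind = rng.choice(["benign_missense", "synonymous", "common", "lowqual", "intronic"],
                      p=[0.35, 0.2, 0.2, 0.1, 0.15])
    if kind == "intronic":
        s, e = tx.exons[int(rng.integers(0, len(tx.exons) - 1))]
        pos = e + int(rng.integers(5, 40))  # deep intronic, beyond canonical sites
        rec = VariantRecord(
            chrom=tx.chrom, pos=pos, ref="C", alt="T", gene=gene,
            exon=tx.exon_number(e), region=Region.INTRONIC,
            pop_af=float(rng.uniform(0, 0.05)),
        )
        _quality_fields(rec, rng, good=True)
        return rec
    outcome = "synonymous" if kind == "synonymous" else "missense"
    pos, ref, alt, exon = _snv_for_outcome(tx, rng, outcome)
    rec = VariantRecord(
        chrom=tx.chrom, pos=pos, ref=ref, alt=alt, gene=gene, exon=exon,
        dbsnp_id=f"rs{int(rng.integers(10**6, 10**8))}",
    )
    rec.pop_af = (
        float(rng.uniform(0.011, 0.3)) if kind == "common" else float(rng.uniform(0, 0.009))
    )
    _quality_fields(rec, rng, good=kind != "lowqual")
    _sample_scores(rec, cfg, rng, damaging=False)
    return rec


# ---------------------------------------------------------------------------
# Pedigrees


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _make_family(
    fid: str,
    carrier_keys: list[str],
    causal_key: Optional[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> Family:
    """Pedigree with Mendelian transmission of each carried variant.

    Each variant enters through one (possibly unsampled) transmitting
    parent; siblings inherit with probability 1/2.  Carriers are affected
    once past the penetrance age; affection of carrier-negative members is
    unaffected.  Relatives are typed with probability ``typed_prob``.
    """
    proband = PedigreeIndividual(
        family_id=fid,
        individual_id=f"{fid}_P",
        sex=Sex.MALE if rng.random() < cfg.male_prob else Sex.FEMALE,
        affected=Affection.AFFECTED,
        age=_truncnorm(rng, cfg.mean_age, cfg.age_sd, cfg.age_min, cfg.age_max),
    )
    members = [proband]
    has_parents = rng.random() < cfg.parent_prob
    father = mother = None
    transmitting: dict[str, str] = {}
    if has_parents:
        page = proband.age + _truncnorm(rng, 27, 4, 18, 45)
        father = PedigreeIndividual(
            family_id=fid, individual_id=f"{fid}_F", sex=Sex.MALE,
            affected=Affection.UNAFFECTED, age=min(page, 100.0),
        )
        mage = proband.age + _truncnorm(rng, 27, 4, 18, 45)
        mother = PedigreeIndividual(
            family_id=fid, individual_id=f"{fid}_M", sex=Sex.FEMALE,
            affected=Affection.UNAFFECTED, age=min(mage, 100.0),
        )
        proband.father_id = father.individual_id
        proband.mother_id = mother.individual_id
        members += [father, mother]
        for key in carrier_keys:
            transmitting[key] = "F" if rng.random() < 0.5 else "M"

    n_sibs = int(rng.poisson(cfg.sibling_rate))
    sibs = []
    for i in range(n_sibs):
        sib = PedigreeIndividual(
            family_id=fid,
            individual_id=f"{fid}_S{i + 1}",
            sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            affected=Affection.UNAFFECTED,
            age=_truncnorm(rng, proband.age, 8, 18, 95),
            father_id=father.individual_id if father else None,
            mother_id=mother.individual_id if mother else None,
        )
        members.append(sib)
        sibs.append(sib)

    for key in carrier_keys:
        carriers: dict[str, bool] = {proband.individual_id: True}
        if has_parents:
            side = transmitting[key]
            carriers[father.individual_id] = side == "F"
            carriers[mother.individual_id] = side == "M"
        for sib in sibs:
            carriers[sib.individual_id] = bool(rng.random() < 0.5)
        for m in members:
            is_carrier = carriers.get(m.individual_id, False)
            typed = m is proband or rng.random() < cfg.typed_prob
            if typed:
                m.carrier[key] = Carrier.CARRIER if is_carrier else Carrier.NON_CARRIER
            if key == causal_key and m is not proband:
                if is_carrier and m.age is not None and m.age > cfg.penetrance_age:
                    m.affected = Affection.AFFECTED

    return Family(family_id=fid, members=members)


# ---------------------------------------------------------------------------
# Phenotypes


def _group_effect(coefs: dict, group: GenotypeGroup) -> float:
    if group in (GenotypeGroup.PKD1_PT,):
        return 0.0
    if group is GenotypeGroup.NM:
        return coefs.get("PKD2", 0.0)  # NM presents like the mildest genotype
    return coefs.get(group.value, 0.0)


def weibull_scale_for_median(median: float, shape: float) -> float:
    return median / math.log(2) ** (1.0 / shape)


def sample_esrd_ages(
    group: GenotypeGroup | str, n: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw ESRD onset ages for a genotype arm from the Weibull clock."""
    group = GenotypeGroup(group)
    median = cfg.esrd_median_by_group[group.value]
    scale = weibull_scale_for_median(median, cfg.weibull_shape)
    return scale * rng.weibull(cfg.weibull_shape, size=n)


def generate_phenotypes(
    families: list[Family],
    groups: dict[str, GenotypeGroup],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[SubjectPhenotype]:
    """Clinical records for every affected member, drawn from the linear
    phenotype models plus family random intercepts and a Weibull ESRD
    clock.

    log10(htTKV) = const + b_age*age + b_male*male + effect(group) +
    family intercept + noise; eGFR analogously.  Subjects past their drawn
    ESRD age have eGFR recorded as 15 (renal-replacement convention).
    """
    out: list[SubjectPhenotype] = []
    for fam in families:
        group = groups[fam.family_id]
        u_httkv = rng.normal(0.0, cfg.httkv_family_sd)
        u_egfr = rng.normal(0.0, cfg.egfr_family_sd)
        for m in fam.members:
            if m.affected is not Affection.AFFECTED:
                continue
            male = 1.0 if m.sex is Sex.MALE else 0.0
            age = m.age if m.age is not None else cfg.mean_age
            log_httkv = (
                cfg.httkv_coefs["const"]
                + cfg.httkv_coefs["age"] * age
                + cfg.httkv_coefs["male"] * male
                + _group_effect(cfg.httkv_coefs, group)
                + u_httkv
                + rng.normal(0.0, cfg.httkv_residual_sd)
            )
            egfr = (
                cfg.egfr_coefs["const"]
                + cfg.egfr_coefs["age"] * age
                + cfg.egfr_coefs["male"] * male
                + _group_effect(cfg.egfr_coefs, group)
                + u_egfr
                + rng.normal(0.0, cfg.egfr_residual_sd)
            )
            esrd_age_draw = float(sample_esrd_ages(group, 1, cfg, rng)[0])
            esrd = esrd_age_draw <= age
            htn = rng.random() < 0.72
            htn_dx_age = (
                _truncnorm(rng, 38.8, 10.0, 18.0, max(age, 18.5)) if htn else None
            )
            uro_age = (
                _truncnorm(rng, 38.0, 10.0, 18.0, max(age, 18.5))
                if rng.random() < 0.25
                else None
            )
            death = esrd and rng.random() < 0.15
            out.append(
                SubjectPhenotype(
                    subject_id=m.individual_id,
                    family_id=fam.family_id,
                    sex=m.sex,
                    age=age,
                    first_visit_age=max(cfg.age_min, age - float(rng.uniform(3, 9))),
                    htn=htn,
                    htn_dx_age=htn_dx_age,
                    httkv=float(10.0**log_httkv),
                    egfr=15.0 if esrd else float(egfr),
                    esrd=esrd,
                    esrd_age=esrd_age_draw if esrd else None,
                    death=death,
                    death_age=age if death else None,
                    urologic_event_age=uro_age,
                    genotype_group=group,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Depth matrix


def generate_depth_matrix(
    sample_ids: list[str],
    txs: dict[Gene, TranscriptModel],
    cnv_events: list[dict],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> DepthMatrix:
    """Negative-binomial depths with per-sample library and per-exon
    capture factors; injected events multiply depth by 0.5 (het deletion)
    or 1.5 (duplication) over their exon span."""
    exon_cols = [
        f"{gene.value}_{i + 1}" for gene in (Gene.PKD1, Gene.PKD2)
        for i in range(len(txs[gene].exons))
    ]
    lib = np.exp(rng.normal(0.0, cfg.library_factor_sd, size=len(sample_ids)))
    cap = np.exp(rng.normal(0.0, cfg.capture_factor_sd, size=len(exon_cols)))
    mu = cfg.depth_mean * np.outer(lib, cap)
    for ev in cnv_events:
        if not ev.get("in_depth", True):
            continue
        try:
            si = sample_ids.index(ev["sample_id"])
        except ValueError:
            continue
        factor = 0.5 if ev["type"] == "deletion" else 1.5
        for exon in range(ev["exon_start"], ev["exon_end"] + 1):
            mu[si, exon_cols.index(f"{ev['gene']}_{exon}")] *= factor
    size = cfg.depth_nb_size
    if not math.isfinite(size):  # degenerate noise-free configuration
        depth = np.rint(mu).astype(int)
    else:
        p = size / (size + mu)
        depth = rng.negative_binomial(size, p)
    return DepthMatrix(
        depth=pd.DataFrame(depth, index=list(sample_ids), columns=exon_cols)
    )


# ---------------------------------------------------------------------------
# Whole-cohort generation


def generate_cohort(cfg: GeneratorConfig) -> CohortBundle:
    """Generate the full joined dataset plus a truth record per family.

    Per family: a genotype group (or NM), a causal variant of a class
    consistent with the group, Mendelian transmission through a sampled
    pedigree, benign decoy variants, phenotypes for affected members, a
    depth matrix over proband samples with injected large events, MLPA
    rows for every true large event, and a known-variant database covering
    the previously established fraction of causal variants.
    """
    rng = np.random.default_rng(cfg.seed)
    txs = {
        Gene.PKD1: build_toy_transcript(Gene.PKD1, rng),
        Gene.PKD2: build_toy_transcript(Gene.PKD2, rng),
    }
    families: list[Family] = []
    groups: dict[str, GenotypeGroup] = {}
    variants: dict[str, VariantRecord] = {}
    known_entries: dict[str, tuple[Grade, str]] = {}
    sanger: dict[str, str] = {}
    cnv_events: list[dict] = []
    truth_families: dict[str, dict] = {}

    n_subjects = 0
    i = 0
    while True:
        if cfg.n_subjects_target is None:
            if i >= cfg.n_families:
                break
        elif n_subjects >= cfg.n_subjects_target:
            break
        i += 1
        fid = f"F{i:04d}"
        if rng.random() < cfg.nm_fraction:
            group = GenotypeGroup.NM
            spec = None
        else:
            group = _DETECTED_GROUPS[
                rng.choice(len(_DETECTED_GROUPS), p=cfg.genotype_group_probs)
            ]
            spec = _sample_causal(group, txs, cfg, rng)
        groups[fid] = group

        decoys = [_sample_decoy(txs, cfg, rng) for _ in range(rng.poisson(cfg.decoy_rate))]
        carrier_keys: list[str] = []
        causal_key = None
        if spec is not None and spec.record is not None:
            causal_key = spec.record.key
            carrier_keys.append(causal_key)
        carrier_keys += [d.key for d in decoys]
        fam = _make_family(fid, carrier_keys, causal_key, cfg, rng)
        families.append(fam)

        tes_keys = list(dict.fromkeys(d.key for d in decoys))
        for d in decoys:
            variants.setdefault(d.key, d)
        expected_stage = "none"
        if spec is not None:
            if spec.record is not None:
                variants.setdefault(causal_key, spec.record)
                if spec.via_sanger:
                    sanger[fid] = causal_key
                    expected_stage = "sanger_exon1"
                else:
                    tes_keys.insert(0, causal_key)
                    expected_stage = "tes"
                if rng.random() < cfg.known_fraction:
                    label = Grade(
                        ("DP", "HLP", "LP")[
                            rng.choice(3, p=cfg.known_label_probs)
                        ]
                    )
                    known_entries[causal_key] = (label, "registry")
            else:  # large deletion/duplication realised in depth +/- MLPA
                gene = Gene.PKD2 if group is GenotypeGroup.PKD2 else Gene.PKD1
                ev = {
                    "sample_id": f"{fid}_P",
                    "family_id": fid,
                    "gene": gene.value,
                    "exon_start": spec.cnv_span[0],
                    "exon_end": spec.cnv_span[1],
                    "type": spec.cnv_type,
                    "in_depth": spec.depth_detectable,
                }
                cnv_events.append(ev)
                expected_stage = "tes" if spec.depth_detectable else "mlpa"
        fam.variants = tes_keys
        truth_families[fid] = {
            "group": group.value,
            "causal_key": causal_key,
            "causal_class": None if spec is None else spec.vclass.value,
            "expected_stage": expected_stage,
        }
        n_subjects += sum(1 for m in fam.members if m.affected is Affection.AFFECTED)

    phenotypes = generate_phenotypes(families, groups, cfg, rng)
    depth = None
    if cfg.with_depth:
        depth = generate_depth_matrix(
            [f"{f.family_id}_P" for f in families], txs, cnv_events, cfg, rng
        )
    mlpa = pd.DataFrame(
        [
            {
                "sample_id": ev["sample_id"],
                "gene": ev["gene"],
                "exon_start": ev["exon_start"],
                "exon_end": ev["exon_end"],
                "result": ev["type"],
            }
            for ev in cnv_events
        ],
        columns=["sample_id", "gene", "exon_start", "exon_end", "result"],
    )
    truth = {
        "seed": cfg.seed,
        "families": truth_families,
        "cnv_events": cnv_events,
        "httkv_coefs": cfg.httkv_coefs,
        "egfr_coefs": cfg.egfr_coefs,
        "esrd_median_by_group": cfg.esrd_median_by_group,
    }
    return CohortBundle(
        families=families,
        variants=variants,
        phenotypes=phenotypes,
        depth=depth,
        mlpa=mlpa,
        known_db=KnownVariantDB(known_entries),
        transcripts={g.value: tx for g, tx in txs.items()},
        sanger_exon1=sanger,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Bundle persistence


def write_bundle(bundle: CohortBundle, outdir) -> None:
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_variants(outdir / "variants.vcf", bundle.variants.values())
    pio.write_pedigree(outdir / "pedigree.ped", bundle.families)
    pio.write_carriers(outdir / "carriers.tsv", bundle.families)
    pio.write_phenotypes(outdir / "phenotypes.csv", bundle.phenotypes)
    if bundle.depth is not None:
        pio.write_depth_matrix(outdir / "depth.tsv", bundle.depth)
    if bundle.mlpa is not None:
        bundle.mlpa.to_csv(outdir / "mlpa.tsv", sep="\t", index=False)
    if bundle.known_db is not None:
        pio.write_known_db(outdir / "known_db.tsv", bundle.known_db)
    with open(outdir / "transcripts.json", "w") as fh:
        json.dump({g: tx.to_dict() for g, tx in bundle.transcripts.items()}, fh)
    extra = {"sanger_exon1": bundle.sanger_exon1, "family_variants": {
        f.family_id: f.variants for f in bundle.families}}
    pio.save_json(outdir / "truth.json", {**bundle.truth, **extra})


def load_bundle(outdir) -> CohortBundle:
    from . import io as pio

    outdir = Path(outdir)
    records = pio.read_variants(outdir / "variants.vcf")
    variants = {r.key: r for r in records}
    families = pio.read_pedigree(outdir / "pedigree.ped", outdir / "carriers.tsv")
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    fam_variants = truth.pop("family_variants", {})
    sanger = truth.pop("sanger_exon1", {})
    for f in families:
        f.variants = fam_variants.get(f.family_id, f.variants)
    with open(outdir / "transcripts.json") as fh:
        txs = {g: TranscriptModel.from_dict(d) for g, d in json.load(fh).items()}
    depth_path = outdir / "depth.tsv"
    depth = pio.read_depth_matrix(depth_path) if depth_path.exists() else None
    mlpa_path = outdir / "mlpa.tsv"
    mlpa = pio.read_mlpa(mlpa_path) if mlpa_path.exists() else None
    return CohortBundle(
        families=families,
        variants=variants,
        phenotypes=pio.read_phenotypes(outdir / "phenotypes.csv"),
        depth=depth,
        mlpa=mlpa,
        known_db=pio.read_known_db(outdir / "known_db.tsv"),
        transcripts=txs,
        sanger_exon1=sanger,
        truth=truth,
    )
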