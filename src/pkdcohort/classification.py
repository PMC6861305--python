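"""Consequence classification and pathogenicity grading.

Variants are classified into seven consequence categories (nonsense,
frameshift, typical splicing, large deletion/duplication, missense, small
in-frame indel, no variant) from first principles against a transcript
model, then graded on the five-grade pathogenicity scale (DP, HLP, LP, LN,
I).  Truncating consequences grade DP outright; missense and in-frame
changes are arbitrated by a 2-of-3 in-silico rule (SIFT <= 0.05,
PolyPhen-2 damaging, GERP++ >= 4) together with familial segregation
evidence.  Graded mutations finally map to the four prognostic genotype
groups (PKD1-PT / PKD1-ID / PKD1-NT / PKD2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .models import (
    Gene,
    Grade,
    KnownStatus,
    PolyPhenCall,
    Region,
    SegregationStatus,
    TRUNCATING_CLASSES,
    VariantClass,
    VariantRecord,
)

__all__ = [
    "CODON_TABLE",
    "TranscriptModel",
    "Consequence",
    "OutOfTranscriptError",
    "classify_consequence",
    "annotate_consequence",
    "InsilicoVerdict",
    "insilico_verdict",
    "assign_grade",
    "assign_genotype_group",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: Standard genetic code, '*' marks stop codons.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class OutOfTranscriptError(ValueError):
    """Variant lies outside the transcript footprint (+/- 2 bp)."""


class Consequence(str, Enum):
    """classify_consequence outcome: the seven-class scheme plus a
    synonymous marker consumed only by the prioritization filter."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    TYPICAL_SPLICING = "typical_splicing"
    LARGE_DEL_DUP = "large_del_dup"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"

    def to_variant_class(self) -> VariantClass:
        if self is Consequence.SYNONYMOUS:
            raise ValueError("synonymous marker has no variant class")
        return VariantClass(self.value)


@dataclass
class TranscriptModel:
    """Minimal transcript: ordered exon intervals on the genome plus the
    spliced coding-strand sequence.

    ``exons`` are 1-based inclusive genomic intervals in *transcript* order
    (descending genomic coordinates on the minus strand).  ``sequence`` is
    the spliced transcript on the coding strand; ``cds_start``/``cds_end``
    are the genomic coordinates of the first and last CDS base in
    transcript order.
    """

    gene: Gene
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str
    chrom: str = ""

    # derived
    _cds_lo: int = field(init=False, repr=False, default=0)
    _cds_hi: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exon intervals overlap")
        genomic_order = sorted(self.exons) if self.strand == "+" else sorted(self.exons, reverse=True)
        if list(self.exons) != genomic_order:
            raise ValueError("exons must be listed in transcript order")
        if sum(e - s + 1 for s, e in self.exons) != len(self.sequence):
            raise ValueError("sequence length does not match exon spans")
        self._cds_lo = self.tx_index(self.cds_start)
        self._cds_hi = self.tx_index(self.cds_end)
        if self._cds_lo is None or self._cds_hi is None or self._cds_lo > self._cds_hi:
            raise ValueError("CDS bounds must be exonic and ordered in transcript space")
        cds = self.cds_sequence
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        protein = translate(cds)
        if "*" in protein[:-1]:
            raise ValueError("CDS translation has an internal stop")

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self._cds_lo : self._cds_hi + 1]

    def tx_index(self, pos: int) -> Optional[int]:
        """0-based transcript coordinate of a genomic position, or None."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def genomic_pos(self, tx_idx: int) -> int:
        """Inverse of :meth:`tx_index`."""
        offset = 0
        for s, e in self.exons:
            length = e - s + 1
            if tx_idx < offset + length:
                within = tx_idx - offset
                return s + within if self.strand == "+" else e - within
            offset += length
        raise IndexError(tx_idx)

    def exon_number(self, pos: int) -> Optional[int]:
        """1-based transcript-relative exon index containing ``pos``."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def canonical_splice_positions(self) -> frozenset[int]:
        """Genomic positions at the canonical +/-1, +/-2 intronic sites."""
        spans = sorted(self.exons)
        lo, hi = spans[0][0], spans[-1][1]
        sites: set[int] = set()
        for s, e in spans:
            for p in (s - 1, s - 2, e + 1, e + 2):
                if lo <= p <= hi and self.tx_index(p) is None:
                    sites.add(p)
        return frozenset(sites)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene.value,
            "strand": self.strand,
            "exons": [list(x) for x in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "sequence": self.sequence,
            "chrom": self.chrom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            gene=Gene(d["gene"]),
            strand=d["strand"],
            exons=[tuple(x) for x in d["exons"]],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
            sequence=d["sequence"],
            chrom=d.get("chrom", ""),
        )


def translate(cds: str) -> str:
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def classify_consequence(variant: VariantRecord, tx: TranscriptModel) -> Consequence:
    """Classify one variant against a transcript model.

    Classification is local: a SNV is judged by its own codon, an indel by
    its length modulo 3, a symbolic or whole-exon-spanning event as a large
    deletion/duplication, and the canonical +/-1, +/-2 intronic positions
    as typical splicing.
    """
    if variant.is_symbolic:
        return Consequence.LARGE_DEL_DUP

    ref, alt = variant.ref, variant.alt
    pos = variant.pos

    if len(ref) > 1:
        span = (pos, pos + len(ref) - 1)
        for s, e in tx.exons:
            if span[0] <= s and e <= span[1]:
                return Consequence.LARGE_DEL_DUP

    if pos in tx.canonical_splice_positions():
        return Consequence.TYPICAL_SPLICING

    t = tx.tx_index(pos)
    if t is None:
        raise OutOfTranscriptError(
            f"{variant.key} is outside the {tx.gene.value} transcript footprint"
        )

    if len(ref) != len(alt):  # indel, VCF-style left-anchored
        diff = len(alt) - len(ref)
        if diff % 3 != 0:
            return Consequence.FRAMESHIFT
        return Consequence.INFRAME_INDEL

    # SNV on the coding strand
    ref_b, alt_b = ref, alt
    if tx.strand == "-":
        ref_b, alt_b = ref.translate(_COMP), alt.translate(_COMP)
    c = t - tx._cds_lo
    if c < 0 or c >= len(tx.cds_sequence):
        raise OutOfTranscriptError(f"{variant.key} falls outside the coding region")
    cds = tx.cds_sequence
    if cds[c] != ref_b:
        raise ValueError(
            f"{variant.key}: reference allele {ref_b!r} does not match transcript "
            f"base {cds[c]!r}"
        )
    codon_idx = c // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[: c % 3] + alt_b + codon[c % 3 + 1 :]
    aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutated]
    if aa_alt == aa_ref:
        return Consequence.SYNONYMOUS
    if aa_alt == "*":
        return Consequence.NONSENSE
    return Consequence.MISSENSE


def annotate_consequence(variant: VariantRecord, tx: TranscriptModel) -> Consequence:
    """Classify and write the outcome back onto the record (vclass,
    synonymous flag, region, in-frame indel length)."""
    cons = classify_consequence(variant, tx)
    if cons is Consequence.SYNONYMOUS:
        variant.synonymous = True
        variant.vclass = None
    else:
        variant.synonymous = False
        variant.vclass = cons.to_variant_class()
        if cons is Consequence.INFRAME_INDEL:
            variant.indel_aa_len = abs(len(variant.alt) - len(variant.ref)) // 3
    if cons is Consequence.TYPICAL_SPLICING:
        variant.region = Region.SPLICING
    return cons


# ---------------------------------------------------------------------------
# In-silico verdict and grading


@dataclass(frozen=True)
class InsilicoVerdict:
    """2-of-3 rule over SIFT, PolyPhen-2 (HumDiv) and GERP++.

    An absent score is a non-hit; it never blocks grading.
    """

    sift_hit: bool
    pp2_hit: bool
    gerp_hit: bool

    @property
    def damaging(self) -> bool:
        return (self.sift_hit + self.pp2_hit + self.gerp_hit) >= 2


def insilico_verdict(
    variant: VariantRecord, sift_max: float = 0.05, gerp_min: float = 4.0
) -> InsilicoVerdict:
    return InsilicoVerdict(
        sift_hit=variant.sift is not None and variant.sift <= sift_max,
        pp2_hit=variant.polyphen_call is PolyPhenCall.DAMAGING,
        gerp_hit=variant.gerp is not None and variant.gerp >= gerp_min,
    )


def assign_grade(
    vclass: VariantClass,
    known_status: KnownStatus = KnownStatus.NONE,
    verdict: Optional[InsilicoVerdict] = None,
    segregation: SegregationStatus = SegregationStatus.UNTESTED,
) -> Grade:
    """Five-grade decision tree, evaluated in order.

    1. Truncating consequence, or database-established DP -> DP.
    2. Database-established HLP -> HLP; LP -> LP (novel variants only are
       re-arbitrated by segregation).
    3. Novel damaging missense/in-frame: segregation positive -> HLP,
       negative -> LN, otherwise -> LP.
    4. Novel non-damaging missense/in-frame: segregation negative -> LN,
       otherwise -> I.
    5. No variant -> NV.
    """
    if vclass is None:
        raise ValueError("variant class must be assigned before grading")
    vclass = VariantClass(vclass)
    known_status = KnownStatus(known_status)
    segregation = SegregationStatus(segregation)

    if vclass in TRUNCATING_CLASSES or known_status is KnownStatus.DP:
        return Grade.DP
    if known_status is KnownStatus.HLP:
        return Grade.HLP
    if known_status is KnownStatus.LP:
        return Grade.LP
    if vclass in (VariantClass.MISSENSE, VariantClass.INFRAME_INDEL):
        damaging = verdict is not None and verdict.damaging
        if damaging:
            if segregation is SegregationStatus.POSITIVE:
                return Grade.HLP
            if segregation is SegregationStatus.NEGATIVE:
                return Grade.LN
            return Grade.LP
        if segregation is SegregationStatus.NEGATIVE:
            return Grade.LN
        return Grade.I
    return Grade.NV  # no_variant


def assign_genotype_group(
    gene: Gene,
    vclass: Optional[VariantClass],
    indel_aa_len: int = 0,
    grade: Optional[Grade] = None,
) -> "GenotypeGroup":
    """Map a graded variant to its prognostic genotype group.

    Only mutations (DP/HLP/LP) resolve to a genotype; anything else is NM.
    PKD1 in-frame indels of fewer than five amino acids form the ID group;
    five or more fall into the residual non-truncating pool.
    """
    from .models import GenotypeGroup, MUTATION_GRADES

    if grade is None or Grade(grade) not in MUTATION_GRADES or vclass is None:
        return GenotypeGroup.NM
    gene = Gene(gene)
    vclass = VariantClass(vclass)
    if gene is Gene.PKD2:
        return GenotypeGroup.PKD2
    if vclass in TRUNCATING_CLASSES:
        return GenotypeGroup.PKD1_PT
    if vclass is VariantClass.INFRAME_INDEL and indel_aa_len < 5:
        return GenotypeGroup.PKD1_ID
    return GenotypeGroup.PKD1_NT
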