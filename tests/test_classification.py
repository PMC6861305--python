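"""Consequence classification vs a translation oracle, the 2-of-3 in-silico
rule, the five-grade decision tree, and genotype grouping."""
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from pkdcohort import (
    Consequence,
    Gene,
    GenotypeGroup,
    Grade,
    InsilicoVerdict,
    KnownStatus,
    SegregationStatus,
    TranscriptModel,
    VariantClass,
    VariantRecord,
    assign_genotype_group,
    assign_grade,
    classify_consequence,
    insilico_verdict,
)
from pkdcohort.classification import OutOfTranscriptError


def snv(tx, pos, ref, alt, exon=1):
    return VariantRecord(chrom=tx.chrom or "16", pos=pos, ref=ref, alt=alt,
                         gene=tx.gene, exon=exon)


# ---------------------------------------------------------------------------
# Independent oracle: apply the edit to the CDS, translate with Biopython,
# and classify from the full-protein diff.


def oracle_classify(tx, pos, ref, alt):
    t = tx.tx_index(pos)
    assert t is not None
    cds_lo = tx.tx_index(tx.cds_start)
    c = t - cds_lo
    cds = str(tx.sequence[cds_lo : tx.tx_index(tx.cds_end) + 1])
    assert cds[c : c + len(ref)] == ref
    mutated = cds[:c] + alt + cds[c + len(ref):]
    if (len(alt) - len(ref)) % 3 != 0:
        return "frameshift"
    if len(alt) != len(ref):
        return "inframe_indel"
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutated).translate())
    if p_alt == p_ref:
        return "synonymous"
    diff = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
    return "nonsense" if p_alt[diff[0]] == "*" else "missense"


def test_classifier_matches_translation_oracle_for_all_snvs(toy_tx):
    """Every possible SNV of the toy transcript classifies identically to
    the translate-and-diff oracle."""
    tx = toy_tx
    for t in range(len(tx.sequence)):
        pos = tx.genomic_pos(t)
        ref = tx.sequence[t]
        for alt in "ACGT":
            if alt == ref:
                continue
            got = classify_consequence(snv(tx, pos, ref, alt), tx)
            assert got.value == oracle_classify(tx, pos, ref, alt), (t, ref, alt)


def test_classifier_matches_oracle_for_short_indels(toy_tx):
    """Deletions and insertions of 1-6 bp, anchored inside one exon, agree
    with the oracle on frameshift vs in-frame."""
    tx = toy_tx
    rng = np.random.default_rng(5)
    for length in range(1, 7):
        for _ in range(30):
            s, e = tx.exons[rng.integers(0, len(tx.exons))]
            if e - s + 1 < length + 2:
                continue
            pos = int(rng.integers(s + 1, e - length))
            t = tx.tx_index(pos)
            # deletion
            ref = tx.sequence[t : t + length + 1]
            got = classify_consequence(snv(tx, pos, ref, ref[0]), tx)
            assert got.value == oracle_classify(tx, pos, ref, ref[0])
            # insertion
            ins = ref[0] + "".join(rng.choice(list("ACGT"), size=length))
            got = classify_consequence(snv(tx, pos, ref[0], ins), tx)
            assert got.value == oracle_classify(tx, pos, ref[0], ins)


def _nine_codon_tx():
    # ATG + 7 codons + TAA over 2 exons (codon-aligned split after codon 5)
    seq = "ATG" + "CAT" + "GGT" + "CAA" + "CCT" + "GAA" + "TTC" + "AAA" + "TAA"
    exons = [(101, 115), (201, 212)]
    return TranscriptModel(
        gene=Gene.PKD2, strand="+", exons=exons,
        cds_start=101, cds_end=212, sequence=seq, chrom="4",
    )


class TestWorkedExamples:
    def test_stop_gain_in_codon_four(self):
        tx = _nine_codon_tx()
        # codon 4 is CAA at tx index 9..11 -> genomic 110; C->T makes TAA
        assert tx.sequence[9:12] == "CAA"
        got = classify_consequence(snv(tx, 110, "C", "T"), tx)
        assert got is Consequence.NONSENSE

    def test_three_bp_deletion_removes_one_codon(self):
        tx = _nine_codon_tx()
        # anchor at last base of codon 4, delete codon 5 (CCT)
        pos = 112  # tx index 11
        ref = tx.sequence[11:15]
        got = classify_consequence(snv(tx, pos, ref, ref[0]), tx)
        assert got is Consequence.INFRAME_INDEL

    def test_one_bp_insertion_shifts_frame(self):
        tx = _nine_codon_tx()
        pos = 105  # inside codon 2
        ref = tx.sequence[4]
        got = classify_consequence(snv(tx, pos, ref, ref + "G"), tx)
        assert got is Consequence.FRAMESHIFT

    def test_canonical_donor_position(self):
        tx = _nine_codon_tx()
        got = classify_consequence(snv(tx, 116, "G", "A"), tx)  # exon1 end + 1
        assert got is Consequence.TYPICAL_SPLICING

    def test_symbolic_and_whole_exon_events(self):
        tx = _nine_codon_tx()
        assert (
            classify_consequence(snv(tx, 101, "N", "<DEL>"), tx)
            is Consequence.LARGE_DEL_DUP
        )
        # literal deletion spanning all of exon 2
        long_ref = "A" * (212 - 200 + 3)
        rec = VariantRecord(chrom="4", pos=200, ref=long_ref, alt="A",
                            gene=Gene.PKD2, exon=2)
        assert classify_consequence(rec, tx) is Consequence.LARGE_DEL_DUP

    def test_outside_footprint_raises(self):
        tx = _nine_codon_tx()
        with pytest.raises(OutOfTranscriptError):
            classify_consequence(snv(tx, 150, "A", "G"), tx)


def test_minus_strand_snv_uses_complemented_alleles():
    # minus-strand transcript: coding sequence ATG GAA TAA; genomic plus
    # strand therefore carries the reverse complement
    seq = "ATGGAATAA"
    tx = TranscriptModel(
        gene=Gene.PKD1, strand="-", exons=[(201, 209)],
        cds_start=209, cds_end=201, sequence=seq, chrom="16",
    )
    # codon 2 GAA -> TAA needs coding G->T at tx index 3, genomic pos 206,
    # plus-strand alleles C->A
    got = classify_consequence(snv(tx, 206, "C", "A"), tx)
    assert got is Consequence.NONSENSE


# ---------------------------------------------------------------------------
# In-silico verdict


@pytest.mark.parametrize(
    "sift, pp2, gerp, damaging",
    [
        (0.01, "damaging", 5.2, True),
        (0.05, "benign", 4.0, True),  # two inclusive boundary hits
        (None, "damaging", 3.9, False),  # single hit
        (None, None, None, False),
        (0.06, "damaging", 4.0, True),
    ],
)
def test_two_of_three_rule(sift, pp2, gerp, damaging):
    rec = VariantRecord(chrom="16", pos=1, ref="A", alt="G", gene="PKD1", exon=1,
                        sift=sift, polyphen_call=pp2, gerp=gerp)
    v = insilico_verdict(rec)
    assert v.damaging is damaging


# ---------------------------------------------------------------------------
# Grade decision tree


def expected_grade(vclass, known, damaging, seg):
    """Independent flat decision table."""
    truncating = vclass in {"nonsense", "frameshift", "typical_splicing", "large_del_dup"}
    if truncating or known == "DP":
        return Grade.DP
    if known == "HLP":
        return Grade.HLP
    if known == "LP":
        return Grade.LP
    if vclass == "no_variant":
        return Grade.NV
    # novel missense / in-frame indel
    if damaging:
        return {"positive": Grade.HLP, "negative": Grade.LN}.get(seg, Grade.LP)
    return Grade.LN if seg == "negative" else Grade.I


def test_grade_tree_is_total_and_matches_decision_table():
    verdicts = {
        True: InsilicoVerdict(True, True, False),
        False: InsilicoVerdict(True, False, False),
        None: None,
    }
    for vclass, known, dmg, seg in itertools.product(
        VariantClass, KnownStatus, verdicts, SegregationStatus
    ):
        got = assign_grade(vclass, known, verdicts[dmg], seg)
        assert got is expected_grade(vclass.value, known.value, bool(dmg), seg.value)


@pytest.mark.parametrize(
    "vclass, known, damaging, seg, grade",
    [
        ("nonsense", "none", None, "untested", Grade.DP),
        ("missense", "none", True, "positive", Grade.HLP),
        ("missense", "none", True, "negative", Grade.LN),
        ("missense", "none", True, "untested", Grade.LP),
        ("missense", "none", False, "untested", Grade.I),
        ("missense", "DP", False, "untested", Grade.DP),  # database DP overrides
    ],
)
def test_grade_examples(vclass, known, damaging, seg, grade):
    verdict = InsilicoVerdict(True, True, False) if damaging else (
        None if damaging is None else InsilicoVerdict(False, False, False))
    assert assign_grade(VariantClass(vclass), KnownStatus(known), verdict,
                        SegregationStatus(seg)) is grade


GRADE_ORDER = {Grade.LN: 0, Grade.I: 1, Grade.LP: 2, Grade.HLP: 3, Grade.DP: 4}


def test_segregation_evidence_moves_grades_monotonically():
    """Positive evidence never lowers a grade, negative never raises one,
    and DP is absorbing."""
    verdicts = [None, InsilicoVerdict(False, False, False), InsilicoVerdict(True, True, True)]
    for vclass, known, verdict in itertools.product(
        [c for c in VariantClass if c is not VariantClass.NO_VARIANT], KnownStatus, verdicts
    ):
        base = assign_grade(vclass, known, verdict, SegregationStatus.UNTESTED)
        pos = assign_grade(vclass, known, verdict, SegregationStatus.POSITIVE)
        neg = assign_grade(vclass, known, verdict, SegregationStatus.NEGATIVE)
        assert GRADE_ORDER[pos] >= GRADE_ORDER[base]
        assert GRADE_ORDER[neg] <= GRADE_ORDER[base]
        if base is Grade.DP:
            assert pos is Grade.DP and neg is Grade.DP


# ---------------------------------------------------------------------------
# Genotype grouping


@pytest.mark.parametrize(
    "gene, vclass, aa_len, grade, group",
    [
        ("PKD1", "inframe_indel", 2, "DP", GenotypeGroup.PKD1_ID),
        ("PKD1", "inframe_indel", 4, "LP", GenotypeGroup.PKD1_ID),
        ("PKD1", "inframe_indel", 5, "LP", GenotypeGroup.PKD1_NT),  # "<5" boundary
        ("PKD1", "nonsense", 0, "DP", GenotypeGroup.PKD1_PT),
        ("PKD1", "missense", 0, "HLP", GenotypeGroup.PKD1_NT),
        ("PKD2", "missense", 0, "LP", GenotypeGroup.PKD2),
        ("PKD2", "nonsense", 0, "DP", GenotypeGroup.PKD2),
        ("PKD1", "missense", 0, "I", GenotypeGroup.NM),  # not a mutation
        ("PKD1", "missense", 0, "LN", GenotypeGroup.NM),
    ],
)
def test_genotype_grouping(gene, vclass, aa_len, grade, group):
    assert assign_genotype_group(Gene(gene), VariantClass(vclass), aa_len,
                                 Grade(grade)) is group
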