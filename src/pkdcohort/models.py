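"""Domain types shared by every pipeline stage.

The object model mirrors how targeted-panel ADPKD genetics is actually
organised: annotated sequence variants, families with per-variant carrier
status, a samples x exons read-depth matrix, and per-subject clinical
records.  Everything downstream (filtering, grading, CNV calling, cohort
statistics) consumes these types.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "Gene",
    "VariantClass",
    "TRUNCATING_CLASSES",
    "Grade",
    "MUTATION_GRADES",
    "KnownStatus",
    "PolyPhenCall",
    "Region",
    "GenotypeGroup",
    "Sex",
    "Affection",
    "Carrier",
    "SegregationStatus",
    "VariantRecord",
    "PedigreeIndividual",
    "Family",
    "DepthMatrix",
    "SubjectPhenotype",
    "DomainInterval",
    "DomainMap",
    "KnownVariantDB",
    "CohortBundle",
    "SchemaError",
    "PedigreeError",
    "FormatError",
]


class SchemaError(ValueError):
    """A file parsed but violated the expected schema."""


class PedigreeError(ValueError):
    """Pedigree structure is inconsistent (dangling parent, cycle...)."""


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


class Gene(str, Enum):
    PKD1 = "PKD1"
    PKD2 = "PKD2"


class VariantClass(str, Enum):
    """Seven consequence categories used for family-level accounting."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    TYPICAL_SPLICING = "typical_splicing"
    LARGE_DEL_DUP = "large_del_dup"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    NO_VARIANT = "no_variant"


#: Classes expected to truncate the protein product.
TRUNCATING_CLASSES = frozenset(
    {
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT,
        VariantClass.TYPICAL_SPLICING,
        VariantClass.LARGE_DEL_DUP,
    }
)


class Grade(str, Enum):
    """Five-grade pathogenicity scale plus the no-variant outcome.

    DP/HLP/LP collectively count as "mutations"; LN and I do not.
    """

    DP = "DP"
    HLP = "HLP"
    LP = "LP"
    LN = "LN"
    I = "I"
    NV = "NV"

    @property
    def is_mutation(self) -> bool:
        return self in MUTATION_GRADES


MUTATION_GRADES = frozenset({Grade.DP, Grade.HLP, Grade.LP})

#: Ordering used for representative-variant precedence (higher = more pathogenic).
GRADE_RANK = {
    Grade.DP: 5,
    Grade.HLP: 4,
    Grade.LP: 3,
    Grade.I: 2,
    Grade.LN: 1,
    Grade.NV: 0,
}


class KnownStatus(str, Enum):
    """Outcome of a known-variant database lookup."""

    DP = "DP"
    HLP = "HLP"
    LP = "LP"
    NONE = "none"


class PolyPhenCall(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"


class Region(str, Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


class GenotypeGroup(str, Enum):
    PKD1_PT = "PKD1_PT"
    PKD1_ID = "PKD1_ID"
    PKD1_NT = "PKD1_NT"
    PKD2 = "PKD2"
    NM = "NM"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Carrier(str, Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    UNTYPED = "untyped"


class SegregationStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"
    UNTESTED = "untested"


@dataclass
class VariantRecord:
    """One annotated sequence variant (one alt allele at one site).

    Coordinates are 1-based inclusive.  Missing optional annotations are
    ``None`` ("absent"), never a numeric default.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Gene
    exon: int
    qual: Optional[float] = None
    genotype_quality: Optional[float] = None
    mapping_quality: Optional[float] = None
    pop_af: Optional[float] = None
    dbsnp_id: Optional[str] = None
    hgvs_c: str = ""
    hgvs_p: str = ""
    sift: Optional[float] = None
    polyphen_call: Optional[PolyPhenCall] = None
    gerp: Optional[float] = None
    known_status: KnownStatus = KnownStatus.NONE
    vclass: Optional[VariantClass] = None
    grade: Optional[Grade] = None
    indel_aa_len: int = 0
    region: Region = Region.EXONIC
    synonymous: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.exon < 1:
            raise ValueError(f"exon must be >= 1, got {self.exon}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af out of [0,1]: {self.pop_af}")
        if self.sift is not None and not (0.0 <= self.sift <= 1.0):
            raise ValueError(f"sift out of [0,1]: {self.sift}")
        if self.indel_aa_len < 0:
            raise ValueError("indel_aa_len must be >= 0")
        self.gene = Gene(self.gene)
        if self.polyphen_call is not None:
            self.polyphen_call = PolyPhenCall(self.polyphen_call)
        self.known_status = KnownStatus(self.known_status)
        self.region = Region(self.region)
        if self.vclass is not None:
            self.vclass = VariantClass(self.vclass)
        if self.grade is not None:
            self.grade = Grade(self.grade)

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_symbolic(self) -> bool:
        """True for symbolic structural alleles such as ``<DEL>``/``<DUP>``."""
        return self.alt.startswith("<")

    @property
    def is_indel(self) -> bool:
        return not self.is_symbolic and len(self.ref) != len(self.alt)


@dataclass
class PedigreeIndividual:
    family_id: str
    individual_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.FEMALE
    affected: Affection = Affection.UNKNOWN
    age: Optional[float] = None
    carrier: dict[str, Carrier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.affected = Affection(self.affected)

    def carrier_status(self, variant_key: str) -> Carrier:
        return self.carrier.get(variant_key, Carrier.UNTYPED)


@dataclass
class Family:
    """A pedigree with its detected variants; the unit of detection accounting."""

    family_id: str
    members: list[PedigreeIndividual]
    variants: list[str] = field(default_factory=list)
    resolved_genotype: Optional[GenotypeGroup] = None
    detection_stage: Optional[str] = None  # tes | sanger_exon1 | mlpa | none

    def __post_init__(self) -> None:
        if not self.members:
            raise PedigreeError(f"family {self.family_id} has no members")
        ids = set()
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"member {m.individual_id} belongs to family {m.family_id}, "
                    f"not {self.family_id}"
                )
            ids.add(m.individual_id)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise PedigreeError(
                        f"family {self.family_id}: parent id {pid!r} of "
                        f"{m.individual_id!r} not found in family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.individual_id: m for m in self.members}
        for start in by_id:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                m = by_id[cur]
                for pid in (m.father_id, m.mother_id):
                    if pid is None:
                        continue
                    if pid == start:
                        raise PedigreeError(
                            f"family {self.family_id}: cyclic pedigree through "
                            f"{start!r}"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def get(self, individual_id: str) -> PedigreeIndividual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)


@dataclass
class DepthMatrix:
    """Samples x exons integer read depths.

    Exon columns are labelled ``GENE_exonIndex`` (e.g. ``PKD1_12``); the
    underlying frame is rectangular by construction.
    """

    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if self.depth.size and (self.depth.values < 0).any():
            raise ValueError("read depths must be non-negative")
        if self.depth.columns.duplicated().any():
            raise ValueError("duplicate exon ids in depth matrix")
        if self.depth.index.duplicated().any():
            raise ValueError("duplicate sample ids in depth matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depth.index)

    @property
    def exon_ids(self) -> list[str]:
        return list(self.depth.columns)


@dataclass
class SubjectPhenotype:
    """Per-person clinical record linked to a family and genotype group.

    ``egfr`` of subjects on renal replacement therapy is recorded as 15
    mL/min/1.73 m2 by convention.
    """

    subject_id: str
    family_id: str
    sex: Sex
    age: float
    first_visit_age: Optional[float] = None
    htn: bool = False
    htn_dx_age: Optional[float] = None
    httkv: Optional[float] = None
    egfr: Optional[float] = None
    esrd: bool = False
    esrd_age: Optional[float] = None
    death: bool = False
    death_age: Optional[float] = None
    urologic_event_age: Optional[float] = None
    genotype_group: Optional[GenotypeGroup] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.genotype_group is not None:
            self.genotype_group = GenotypeGroup(self.genotype_group)
        if self.httkv is not None and self.httkv <= 0:
            raise ValueError("httkv must be > 0 when present")
        if (
            self.esrd_age is not None
            and self.death_age is not None
            and self.esrd_age > self.death_age
        ):
            raise ValueError("esrd_age must be <= death_age")


@dataclass(frozen=True)
class DomainInterval:
    protein: str  # PC1 | PC2
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError("aa_start must be <= aa_end")


class DomainMap:
    """Protein-domain intervals; validated to be non-overlapping per protein."""

    def __init__(self, domains: Iterable[DomainInterval]):
        self.domains = list(domains)
        by_protein: dict[str, list[DomainInterval]] = {}
        for d in self.domains:
            by_protein.setdefault(d.protein, []).append(d)
        for protein, ds in by_protein.items():
            ds = sorted(ds, key=lambda d: d.aa_start)
            for a, b in zip(ds, ds[1:]):
                if b.aa_start <= a.aa_end:
                    raise SchemaError(
                        f"overlapping domains in {protein}: "
                        f"{a.domain_name} and {b.domain_name}"
                    )

    def locate(self, protein: str, aa_pos: int) -> Optional[str]:
        for d in self.domains:
            if d.protein == protein and d.aa_start <= aa_pos <= d.aa_end:
                return d.domain_name
        return None


class KnownVariantDB:
    """Registry of previously established pathogenic variants (DP/HLP/LP)."""

    def __init__(self, entries: Optional[Mapping[str, tuple[Grade, str]]] = None):
        self.entries: dict[str, tuple[Grade, str]] = dict(entries or {})
        for key, (grade, _src) in self.entries.items():
            if grade not in MUTATION_GRADES:
                raise SchemaError(
                    f"known-variant grade for {key} must be DP/HLP/LP, got {grade}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def lookup(self, key: str) -> KnownStatus:
        if key in self.entries:
            return KnownStatus(self.entries[key][0].value)
        return KnownStatus.NONE


@dataclass
class CohortBundle:
    """The joined dataset (synthetic or real) flowing through the pipeline."""

    families: list[Family]
    variants: dict[str, VariantRecord]
    phenotypes: list[SubjectPhenotype] = field(default_factory=list)
    depth: Optional[DepthMatrix] = None
    mlpa: Optional[pd.DataFrame] = None
    known_db: Optional[KnownVariantDB] = None
    transcripts: dict = field(default_factory=dict)
    sanger_exon1: dict[str, str] = field(default_factory=dict)  # family -> variant key
    truth: dict = field(default_factory=dict)
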