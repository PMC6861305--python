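"""Readers and writers for the standard interchange formats.

Variants travel as VCF 4.2 with annotations in INFO fields whose key names
are declared by a :class:`VcfDialect`; pedigrees as 6-column PED (with an
optional 7th age column); depth matrices, known-variant databases, domain
maps and MLPA results as TSV; phenotypes as CSV.  Parsing never silently
coerces a missing annotation to a numeric default.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam
import yaml

from .models import (
    Affection,
    Carrier,
    DepthMatrix,
    DomainInterval,
    DomainMap,
    Family,
    FormatError,
    Gene,
    Grade,
    KnownStatus,
    KnownVariantDB,
    PedigreeError,
    PedigreeIndividual,
    PolyPhenCall,
    Region,
    SchemaError,
    Sex,
    SubjectPhenotype,
    VariantClass,
    VariantRecord,
)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO keys carrying each annotation, plus the transcript
    accessions the exon numbering refers to (declared by the user; panels
    differ in which RefSeq they annotate against)."""

    gene: str = "GENE"
    exon: str = "EXON"
    pop_af: str = "AF_POP"
    sift: str = "SIFT"
    polyphen: str = "PP2"
    gerp: str = "GERP"
    hgvs_c: str = "HGVSC"
    hgvs_p: str = "HGVSP"
    known: str = "KNOWN"
    mapping_quality: str = "MQ"
    region: str = "REGION"
    synonymous: str = "SYN"
    vclass: str = "CLASS"
    grade: str = "GRADE"
    indel_aa_len: str = "AALEN"
    sample_name: str = "PROBAND"
    pkd1_transcript: str = "NM_001009944.3"
    pkd2_transcript: str = "NM_000297.4"


DEFAULT_DIALECT = VcfDialect()

_REQUIRED_INFO = ("gene", "exon")


def _build_header(dialect: VcfDialect) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for contig in ("4", "16"):
        h.contigs.add(contig, length=250_000_000)
    d = dialect
    h.info.add(d.gene, 1, "String", "Gene symbol (PKD1 or PKD2)")
    h.info.add(d.exon, 1, "Integer", "1-based transcript-relative exon index")
    h.info.add(d.pop_af, 1, "Float", "Population allele frequency")
    h.info.add(d.sift, 1, "Float", "SIFT score (damaging <= 0.05)")
    h.info.add(d.polyphen, 1, "String", "PolyPhen-2 HumDiv call (damaging/benign)")
    h.info.add(d.gerp, 1, "Float", "GERP++ conservation score")
    h.info.add(d.hgvs_c, 1, "String", "HGVS coding nomenclature")
    h.info.add(d.hgvs_p, 1, "String", "HGVS protein nomenclature")
    h.info.add(d.known, 1, "String", "Known-variant database status (DP/HLP/LP)")
    h.info.add(d.mapping_quality, 1, "Float", "Mean mapping quality of supporting reads")
    h.info.add(d.region, 1, "String", "Functional region (exonic/splicing/...)")
    h.info.add(d.synonymous, 0, "Flag", "Synonymous coding change")
    h.info.add(d.vclass, 1, "String", "Assigned consequence class")
    h.info.add(d.grade, 1, "String", "Assigned pathogenicity grade")
    h.info.add(d.indel_aa_len, 1, "Integer", "Inserted/deleted amino acids (in-frame)")
    h.info.add("END", 1, "Integer", "End position of structural variant")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("GQ", 1, "Integer", "Genotype quality")
    h.add_sample(dialect.sample_name)
    return h


def write_variants(
    path: PathLike, records: Iterable[VariantRecord], dialect: VcfDialect = DEFAULT_DIALECT
) -> None:
    """Write records as a single-sample VCF 4.2 file (one line per record)."""
    header = _build_header(dialect)
    d = dialect
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
                id=rec.dbsnp_id,
                qual=rec.qual,
            )
            if rec.is_symbolic:
                row.stop = rec.pos
            info = row.info
            info[d.gene] = rec.gene.value
            info[d.exon] = rec.exon
            if rec.pop_af is not None:
                info[d.pop_af] = rec.pop_af
            if rec.sift is not None:
                info[d.sift] = rec.sift
            if rec.polyphen_call is not None:
                info[d.polyphen] = rec.polyphen_call.value
            if rec.gerp is not None:
                info[d.gerp] = rec.gerp
            if rec.hgvs_c:
                info[d.hgvs_c] = rec.hgvs_c
            if rec.hgvs_p:
                info[d.hgvs_p] = rec.hgvs_p
            if rec.known_status is not KnownStatus.NONE:
                info[d.known] = rec.known_status.value
            if rec.mapping_quality is not None:
                info[d.mapping_quality] = rec.mapping_quality
            info[d.region] = rec.region.value
            if rec.synonymous:
                info[d.synonymous] = True
            if rec.vclass is not None:
                info[d.vclass] = rec.vclass.value
            if rec.grade is not None:
                info[d.grade] = rec.grade.value
            if rec.indel_aa_len:
                info[d.indel_aa_len] = rec.indel_aa_len
            gt = row.samples[d.sample_name]
            gt["GT"] = (0, 1)
            if rec.genotype_quality is not None:
                gt["GQ"] = int(round(rec.genotype_quality))
            vcf.write(row)


def read_variants(
    path: PathLike, dialect: VcfDialect = DEFAULT_DIALECT
) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, one per (site, alt allele).

    Missing optional annotations become ``None`` ("absent"), never zero.
    Raises :class:`FormatError` on malformed VCF and :class:`SchemaError`
    when a mandatory INFO key is missing.
    """
    d = dialect
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    records: list[VariantRecord] = []
    with vcf:
        has_sample = d.sample_name in list(vcf.header.samples)
        for line_no, row in enumerate(vcf, start=1):
            info = dict(row.info)
            for field_name in _REQUIRED_INFO:
                key = getattr(d, field_name)
                if key not in info:
                    raise SchemaError(
                        f"{path}: record {line_no} ({row.chrom}:{row.pos}) is "
                        f"missing mandatory INFO key {key!r}"
                    )
            gq = None
            if has_sample:
                sample = row.samples[d.sample_name]
                if sample.get("GQ") is not None:
                    gq = float(sample["GQ"])
            for alt in row.alts or ():
                records.append(
                    VariantRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref,
                        alt=alt,
                        gene=Gene(info[d.gene]),
                        exon=int(info[d.exon]),
                        qual=row.qual,
                        genotype_quality=gq,
                        mapping_quality=_opt_float(info.get(d.mapping_quality)),
                        pop_af=_opt_float(info.get(d.pop_af)),
                        dbsnp_id=row.id,
                        hgvs_c=info.get(d.hgvs_c, ""),
                        hgvs_p=info.get(d.hgvs_p, ""),
                        sift=_opt_float(info.get(d.sift)),
                        polyphen_call=(
                            PolyPhenCall(info[d.polyphen]) if d.polyphen in info else None
                        ),
                        gerp=_opt_float(info.get(d.gerp)),
                        known_status=KnownStatus(info.get(d.known, "none")),
                        vclass=(
                            VariantClass(info[d.vclass]) if d.vclass in info else None
                        ),
                        grade=Grade(info[d.grade]) if d.grade in info else None,
                        indel_aa_len=int(info.get(d.indel_aa_len, 0)),
                        region=Region(info.get(d.region, "exonic")),
                        synonymous=bool(info.get(d.synonymous, False)),
                    )
                )
    return records


def _opt_float(value) -> Optional[float]:
    return None if value is None else float(value)


# ---------------------------------------------------------------------------
# PED + carrier sidecar


def read_pedigree(
    path: PathLike, carriers_path: Optional[PathLike] = None
) -> list[Family]:
    """Read a whitespace-delimited PED file into Family objects.

    Standard 6 columns (family, individual, father, mother, sex, affection
    with 1=unaffected, 2=affected, 0=unknown); a 7th column, when present,
    is read as age in years.  An optional carrier sidecar TSV
    (family_id, individual_id, variant_key, status) fills per-variant
    carrier status.
    """
    try:
        df = pd.read_csv(str(path), sep=r"\s+", header=None, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse PED {path}: {exc}") from exc
    if df.shape[1] < 6:
        raise FormatError(f"{path}: PED needs >= 6 columns, found {df.shape[1]}")

    sex_map = {"1": Sex.MALE, "2": Sex.FEMALE}
    aff_map = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}
    members: dict[str, list[PedigreeIndividual]] = {}
    for _, row in df.iterrows():
        fid, iid, fa, mo, sex, aff = (str(row[i]) for i in range(6))
        age = float(row[6]) if df.shape[1] > 6 and pd.notna(row[6]) else None
        if sex not in sex_map:
            raise FormatError(f"{path}: bad sex code {sex!r} for {iid}")
        if aff not in aff_map:
            raise FormatError(f"{path}: bad affection code {aff!r} for {iid}")
        members.setdefault(fid, []).append(
            PedigreeIndividual(
                family_id=fid,
                individual_id=iid,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=sex_map[sex],
                affected=aff_map[aff],
                age=age,
            )
        )
    families = [Family(family_id=fid, members=ms) for fid, ms in members.items()]
    if carriers_path is not None:
        attach_carriers(families, read_carriers(carriers_path))
    return families


def read_carriers(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    required = {"family_id", "individual_id", "variant_key", "status"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: carrier table missing columns {sorted(missing)}")
    bad = set(df["status"]) - {c.value for c in Carrier}
    if bad:
        raise SchemaError(f"{path}: unknown carrier status values {sorted(bad)}")
    return df


def attach_carriers(families: list[Family], carriers: pd.DataFrame) -> None:
    by_fid = {f.family_id: f for f in families}
    for _, row in carriers.iterrows():
        fam = by_fid.get(str(row["family_id"]))
        if fam is None:
            raise PedigreeError(f"carrier row references unknown family {row['family_id']}")
        fam.get(str(row["individual_id"])).carrier[str(row["variant_key"])] = Carrier(
            row["status"]
        )
        if str(row["variant_key"]) not in fam.variants:
            fam.variants.append(str(row["variant_key"]))


def write_pedigree(path: PathLike, families: Iterable[Family]) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2"}
    aff_code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for fam in families:
            for m in fam.members:
                age = "" if m.age is None else f"\t{m.age:g}"
                fh.write(
                    f"{fam.family_id}\t{m.individual_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{sex_code[m.sex]}\t{aff_code[m.affected]}"
                    f"{age}\n"
                )


def write_carriers(path: PathLike, families: Iterable[Family]) -> None:
    rows = []
    for fam in families:
        for m in fam.members:
            for key, status in m.carrier.items():
                rows.append((fam.family_id, m.individual_id, key, status.value))
    pd.DataFrame(
        rows, columns=["family_id", "individual_id", "variant_key", "status"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Depth matrix


def read_depth_matrix(path: PathLike) -> DepthMatrix:
    """Read a TSV with a header row of exon ids and sample ids in column 1."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty depth matrix file")
        ncol = len(header.split("\t"))
        for i, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise FormatError(f"{path}: ragged row at line {i}")
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: depth matrix has no data rows")
    try:
        df = df.astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric depth cell ({exc})") from exc
    return DepthMatrix(depth=df)


def write_depth_matrix(path: PathLike, m: DepthMatrix) -> None:
    m.depth.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Known-variant database / domain map / MLPA


def read_known_db(path: PathLike) -> KnownVariantDB:
    """Read a TSV of previously established variants (key, grade_label, source)."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    if df.empty:
        return KnownVariantDB({})
    required = {"variant_key", "grade_label", "source"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: known-variant table missing columns {sorted(missing)}")
    entries: dict[str, tuple[Grade, str]] = {}
    for _, row in df.iterrows():
        key = str(row["variant_key"])
        label = str(row["grade_label"])
        if label not in {"DP", "HLP", "LP"}:
            raise SchemaError(f"{path}: grade_label {label!r} for {key} not in DP/HLP/LP")
        grade = Grade(label)
        if key in entries:
            if entries[key][0] is not grade:
                raise SchemaError(
                    f"{path}: conflicting grade labels for duplicate key {key}"
                )
            continue  # identical duplicate -> deduplicate
        entries[key] = (grade, str(row["source"]))
    return KnownVariantDB(entries)


def write_known_db(path: PathLike, db: KnownVariantDB) -> None:
    rows = [(k, g.value, src) for k, (g, src) in db.entries.items()]
    pd.DataFrame(rows, columns=["variant_key", "grade_label", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_map(path: PathLike) -> DomainMap:
    df = pd.read_csv(str(path), sep="\t")
    required = {"protein", "domain_name", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: domain map missing columns {sorted(missing)}")
    return DomainMap(
        DomainInterval(
            protein=str(r["protein"]),
            domain_name=str(r["domain_name"]),
            aa_start=int(r["aa_start"]),
            aa_end=int(r["aa_end"]),
        )
        for _, r in df.iterrows()
    )


def read_mlpa(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", dtype={"sample_id": str, "gene": str, "result": str})
    required = {"sample_id", "gene", "exon_start", "exon_end", "result"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: MLPA table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Phenotypes


_PHENO_COLUMNS = [
    "subject_id",
    "family_id",
    "sex",
    "age",
    "first_visit_age",
    "htn",
    "htn_dx_age",
    "httkv",
    "egfr",
    "esrd",
    "esrd_age",
    "death",
    "death_age",
    "urologic_event_age",
    "genotype_group",
]


def write_phenotypes(path: PathLike, subjects: Iterable[SubjectPhenotype]) -> None:
    rows = []
    for s in subjects:
        d = dataclasses.asdict(s)
        d["sex"] = s.sex.value
        d["genotype_group"] = None if s.genotype_group is None else s.genotype_group.value
        rows.append([d[c] for c in _PHENO_COLUMNS])
    pd.DataFrame(rows, columns=_PHENO_COLUMNS).to_csv(path, index=False)


def read_phenotypes(path: PathLike) -> list[SubjectPhenotype]:
    df = pd.read_csv(str(path))
    missing = set(_PHENO_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: phenotype table missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            SubjectPhenotype(
                subject_id=str(r["subject_id"]),
                family_id=str(r["family_id"]),
                sex=Sex(r["sex"]),
                age=float(r["age"]),
                first_visit_age=_nan_none(r.get("first_visit_age")),
                htn=bool(r.get("htn", False)),
                htn_dx_age=_nan_none(r.get("htn_dx_age")),
                httkv=_nan_none(r.get("httkv")),
                egfr=_nan_none(r.get("egfr")),
                esrd=bool(r.get("esrd", False)),
                esrd_age=_nan_none(r.get("esrd_age")),
                death=bool(r.get("death", False)),
                death_age=_nan_none(r.get("death_age")),
                urologic_event_age=_nan_none(r.get("urologic_event_age")),
                genotype_group=(
                    None
                    if pd.isna(r.get("genotype_group"))
                    else GenotypeGroupSafe(r["genotype_group"])
                ),
            )
        )
    return out


def GenotypeGroupSafe(value):
    from .models import GenotypeGroup

    return GenotypeGroup(str(value))


def _nan_none(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return float(value)


# ---------------------------------------------------------------------------
# Config


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return cfg


def save_json(path: PathLike, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
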