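"""Depth-ratio CNV screening over a targeted-panel exon depth matrix.

The copy-number signal is the two-stage median-normalized depth: each
sample's exon depths are first divided by that sample's median across
exons (library-size correction), then each exon's values by the cohort
median at that exon (capture-efficiency correction).  A diploid background
sits at ratio 1; a heterozygous deletion at ~0.5 and a duplication at
~1.5.  Runs of consecutive out-of-band exons merge into single calls, and
single-exon calls are flagged as needing orthogonal (MLPA) confirmation --
exon-level screens are known to miss or shorten large rearrangements.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import DepthMatrix, Gene

__all__ = [
    "CNVType",
    "CNVCall",
    "CNVThresholds",
    "normalize_depth",
    "call_cnv",
    "reconcile_mlpa",
]

_EXON_ID = re.compile(r"^(?P<gene>[A-Za-z0-9]+)_(?P<idx>\d+)$")


class CNVType(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class CNVThresholds:
    """Calling bands midway between diploid and single-/three-copy ratios."""

    del_threshold: float = 0.65
    dup_threshold: float = 1.35
    min_consecutive_exons: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.del_threshold < 1 < self.dup_threshold):
            raise ValueError("need del_threshold < 1 < dup_threshold")
        if self.min_consecutive_exons < 1:
            raise ValueError("min_consecutive_exons must be >= 1")


@dataclass
class CNVCall:
    sample_id: str
    gene: Gene
    exon_start: int
    exon_end: int
    mean_ratio: float
    call: CNVType
    needs_confirmation: bool = False
    confirmed_by_mlpa: bool = False
    source: str = "depth"

    def __post_init__(self) -> None:
        if self.exon_start > self.exon_end:
            raise ValueError("exon_start must be <= exon_end")

    def overlaps(self, other: "CNVCall") -> bool:
        return (
            self.sample_id == other.sample_id
            and self.gene is other.gene
            and self.call is other.call
            and self.exon_start <= other.exon_end
            and other.exon_start <= self.exon_end
        )


def normalize_depth(m: DepthMatrix) -> pd.DataFrame:
    """Two-stage median normalization; diploid background maps to ratio 1.

    Requires >= 3 samples (the cohort reference is a median), rejects
    all-zero exon columns and zero-median samples.
    """
    df = m.depth
    if df.shape[0] < 3:
        raise ValueError(
            f"cohort normalization needs >= 3 samples, got {df.shape[0]}"
        )
    if (df == 0).all(axis=0).any():
        bad = df.columns[(df == 0).all(axis=0)][0]
        raise ValueError(f"all-zero exon column {bad!r}")
    sample_medians = df.median(axis=1)
    if (sample_medians == 0).any():
        bad = sample_medians.index[sample_medians == 0][0]
        raise ValueError(f"sample {bad!r} has zero median depth")
    stage1 = df.div(sample_medians, axis=0)
    exon_medians = stage1.median(axis=0)
    if (exon_medians == 0).any():
        bad = exon_medians.index[exon_medians == 0][0]
        raise ValueError(f"exon {bad!r} has zero cohort median after stage 1")
    return stage1.div(exon_medians, axis=1)


def _parse_exon_columns(columns: Iterable[str]) -> dict[str, list[tuple[int, str]]]:
    by_gene: dict[str, list[tuple[int, str]]] = {}
    seen: set[tuple[str, int]] = set()
    for col in columns:
        mobj = _EXON_ID.match(str(col))
        if mobj is None:
            raise ValueError(f"exon id {col!r} is not of the form GENE_index")
        gene, idx = mobj["gene"], int(mobj["idx"])
        if (gene, idx) in seen:
            raise ValueError(f"duplicate exon id {col!r}")
        seen.add((gene, idx))
        by_gene.setdefault(gene, []).append((idx, col))
    for cols in by_gene.values():
        cols.sort()
    return by_gene


def call_cnv(
    ratios: pd.DataFrame, thresholds: CNVThresholds = CNVThresholds()
) -> list[CNVCall]:
    """Merge maximal runs of consecutive out-of-band exons into calls.

    A run must be consecutive in exon index (gaps in the panel break runs)
    and uniform in direction.  Single-exon calls are flagged
    ``needs_confirmation``.
    """
    by_gene = _parse_exon_columns(ratios.columns)
    calls: list[CNVCall] = []
    for sample_id in ratios.index:
        for gene, cols in by_gene.items():
            run: list[tuple[int, float]] = []
            run_type: Optional[CNVType] = None

            def flush() -> None:
                if run and len(run) >= thresholds.min_consecutive_exons:
                    calls.append(
                        CNVCall(
                            sample_id=str(sample_id),
                            gene=Gene(gene),
                            exon_start=run[0][0],
                            exon_end=run[-1][0],
                            mean_ratio=float(np.mean([r for _, r in run])),
                            call=run_type,
                            needs_confirmation=len(run) == 1,
                        )
                    )

            prev_idx: Optional[int] = None
            for idx, col in cols:
                r = float(ratios.at[sample_id, col])
                if r < thresholds.del_threshold:
                    this_type = CNVType.DELETION
                elif r > thresholds.dup_threshold:
                    this_type = CNVType.DUPLICATION
                else:
                    this_type = None
                consecutive = prev_idx is not None and idx == prev_idx + 1
                if this_type is None or this_type is not run_type or not consecutive:
                    flush()
                    run, run_type = [], this_type
                if this_type is not None:
                    run.append((idx, r))
                prev_idx = idx
            flush()
    return calls


def reconcile_mlpa(
    calls: list[CNVCall], mlpa: pd.DataFrame
) -> tuple[list[CNVCall], dict[str, list]]:
    """Cross-check depth calls against MLPA results.

    Depth calls matching an MLPA row (same sample and gene, overlapping
    exon range, same direction) are marked confirmed; MLPA-only events are
    appended as calls with ``source="mlpa"``.  The report lists
    discrepancies both ways.
    """
    mlpa_calls = [
        CNVCall(
            sample_id=str(r["sample_id"]),
            gene=Gene(str(r["gene"])),
            exon_start=int(r["exon_start"]),
            exon_end=int(r["exon_end"]),
            mean_ratio=float("nan"),
            call=CNVType(str(r["result"])),
            source="mlpa",
        )
        for _, r in mlpa.iterrows()
    ]
    matched_mlpa: set[int] = set()
    out: list[CNVCall] = []
    depth_only: list[CNVCall] = []
    for call in calls:
        confirmed = False
        for j, mc in enumerate(mlpa_calls):
            if call.overlaps(mc):
                confirmed = True
                matched_mlpa.add(j)
        call.confirmed_by_mlpa = confirmed
        if not confirmed:
            depth_only.append(call)
        out.append(call)
    mlpa_only = [mc for j, mc in enumerate(mlpa_calls) if j not in matched_mlpa]
    for mc in mlpa_only:
        mc.confirmed_by_mlpa = True
        out.append(mc)
    report = {"depth_only": depth_only, "mlpa_only_depth_misses": mlpa_only}
    return out, report
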