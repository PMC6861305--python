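"""Cohort-level accounting and statistics.

Family-level detection rates across sequential assay stages, class/grade
tabulations with shared-variant counts, novelty against a known-variant
database, protein-domain enrichment by adjusted standardized residuals,
ordered trend tests (Jonckheere-Terpstra and linear-by-linear), Kaplan-
Meier medians on the age scale, genotype-phenotype linear models with
family-cluster bootstrap intervals, the PROPKD prognostic score, the Mayo
imaging class, and a one-way intraclass correlation for repeat visits.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps
import statsmodels.formula.api as smf

from .models import (
    Family,
    GenotypeGroup,
    GRADE_RANK,
    Grade,
    Gene,
    KnownVariantDB,
    SubjectPhenotype,
    TRUNCATING_CLASSES,
    VariantClass,
)

__all__ = [
    "rate",
    "DetectionSummary",
    "detection_summary",
    "ClassGradeTable",
    "representative_variant",
    "tabulate_class_grade",
    "novelty_rate",
    "domain_enrichment",
    "jonckheere_terpstra",
    "linear_by_linear",
    "trend_test",
    "km_median",
    "PhenotypeFit",
    "fit_phenotype_model",
    "phenotypes_to_frame",
    "propkd_category",
    "mayo_class",
    "icc_oneway",
]

STAGES = ("tes", "sanger_exon1", "mlpa", "none")


def rate(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at the requested precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Detection accounting


@dataclass
class DetectionSummary:
    n_families: int
    n_with_mutation_tes: int
    n_rescued_sanger_exon1: int
    n_rescued_mlpa: int

    @property
    def n_with_mutation_total(self) -> int:
        return (
            self.n_with_mutation_tes
            + self.n_rescued_sanger_exon1
            + self.n_rescued_mlpa
        )

    @property
    def rate_tes(self) -> float:
        return rate(self.n_with_mutation_tes, self.n_families)

    @property
    def rate_total(self) -> float:
        return rate(self.n_with_mutation_total, self.n_families)


def detection_summary(
    families: Iterable[Union[Family, str]]
) -> DetectionSummary:
    """Tally families by the assay stage that yielded their mutation.

    Accepts Family objects (using ``detection_stage``) or bare stage
    labels; a family counts once regardless of how many mutations it has.
    """
    counts = dict.fromkeys(STAGES, 0)
    n = 0
    for fam in families:
        stage = fam.detection_stage if isinstance(fam, Family) else fam
        stage = stage or "none"
        if stage not in counts:
            raise ValueError(f"unknown detection stage {stage!r}")
        counts[stage] += 1
        n += 1
    if n == 0:
        raise ValueError("empty cohort")
    return DetectionSummary(
        n_families=n,
        n_with_mutation_tes=counts["tes"],
        n_rescued_sanger_exon1=counts["sanger_exon1"],
        n_rescued_mlpa=counts["mlpa"],
    )


# ---------------------------------------------------------------------------
# Class / grade tabulation


_CLASS_ORDER = [c for c in VariantClass]
_GRADE_ORDER = [g for g in Grade]
_CLASS_PRECEDENCE = {  # more truncating first; used only for tie-breaks
    VariantClass.LARGE_DEL_DUP: 0,
    VariantClass.NONSENSE: 1,
    VariantClass.FRAMESHIFT: 2,
    VariantClass.TYPICAL_SPLICING: 3,
    VariantClass.INFRAME_INDEL: 4,
    VariantClass.MISSENSE: 5,
    VariantClass.NO_VARIANT: 6,
}


@dataclass
class ClassGradeTable:
    """Per-gene consequence-class and grade counts over families.

    ``class_shared``/``grade_shared`` count, per cell, the families whose
    representative variant is shared with at least one other family.
    """

    class_counts: pd.DataFrame
    grade_counts: pd.DataFrame
    class_shared: pd.DataFrame = field(default_factory=pd.DataFrame)
    grade_shared: pd.DataFrame = field(default_factory=pd.DataFrame)

    def modal_class(self, gene: str) -> tuple[str, int]:
        """Most frequent class for a gene and its integer percentage share."""
        row = self.class_counts.loc[gene].drop(
            labels=[VariantClass.NO_VARIANT.value], errors="ignore"
        )
        total = int(row.sum())
        label = row.idxmax()
        return str(label), int(rate(int(row[label]), total, decimals=0))

    @property
    def total_families(self) -> int:
        return int(self.class_counts.values.sum())


def representative_variant(variants: Sequence) -> Optional[object]:
    """Pick a family's single representative mutation.

    Precedence: highest grade, then PKD1 over PKD2, then the most
    truncating class.  Returns None for an empty list.
    """
    if not variants:
        return None
    return min(
        variants,
        key=lambda v: (
            -GRADE_RANK[v.grade or Grade.NV],
            0 if v.gene is Gene.PKD1 else 1,
            _CLASS_PRECEDENCE.get(v.vclass, 9),
        ),
    )


def tabulate_class_grade(
    variants_by_family: Mapping[str, Sequence],
) -> ClassGradeTable:
    """Build the per-gene class and grade tables from graded variants.

    ``variants_by_family`` maps family id to that family's graded records;
    families mapping to an empty list count as NV.  Families with several
    graded mutations resolve to one representative by the precedence rule.
    """
    rows = ["PKD1", "PKD2", "NM"]
    class_cols = [c.value for c in _CLASS_ORDER]
    grade_cols = [g.value for g in _GRADE_ORDER]
    cc = pd.DataFrame(0, index=rows, columns=class_cols)
    gc = pd.DataFrame(0, index=rows, columns=grade_cols)
    cs = pd.DataFrame(0, index=rows, columns=class_cols)
    gs = pd.DataFrame(0, index=rows, columns=grade_cols)

    reps: dict[str, object] = {}
    for fid, variants in variants_by_family.items():
        mutations = [v for v in variants if v.grade is not None and v.grade.is_mutation]
        pool = mutations or [v for v in variants if v.grade is not None]
        reps[fid] = representative_variant(pool)

    key_counts: dict[str, int] = {}
    for rep in reps.values():
        if rep is not None:
            key_counts[rep.key] = key_counts.get(rep.key, 0) + 1

    for fid, rep in reps.items():
        if rep is None:
            cc.loc["NM", VariantClass.NO_VARIANT.value] += 1
            gc.loc["NM", Grade.NV.value] += 1
            continue
        gene_row = rep.gene.value if rep.grade.is_mutation else "NM"
        shared = key_counts[rep.key] >= 2
        cc.loc[gene_row, rep.vclass.value] += 1
        gc.loc[gene_row, rep.grade.value] += 1
        if shared:
            cs.loc[gene_row, rep.vclass.value] += 1
            gs.loc[gene_row, rep.grade.value] += 1
    return ClassGradeTable(class_counts=cc, grade_counts=gc, class_shared=cs, grade_shared=gs)


def novelty_rate(
    mutation_keys: Iterable[str], db: KnownVariantDB
) -> tuple[int, float]:
    """Count distinct mutations absent from the known-variant database."""
    keys = list(dict.fromkeys(mutation_keys))
    if not keys:
        raise ValueError("no mutations supplied")
    novel = [k for k in keys if k not in db]
    return len(novel), rate(len(novel), len(keys))


# ---------------------------------------------------------------------------
# Domain enrichment


def domain_enrichment(
    cohort_counts: Mapping[str, int] | pd.Series,
    reference_counts: Mapping[str, int] | pd.Series,
    cutoff: float = 2.58,
) -> pd.DataFrame:
    """Adjusted standardized residuals of the 2 x k (cohort vs reference
    by domain) contingency table, flagged at ``|residual| > cutoff``.

    residual = (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N)).
    """
    cohort = pd.Series(cohort_counts, dtype=float)
    reference = pd.Series(reference_counts, dtype=float)
    if list(cohort.index) != list(reference.index):
        reference = reference.reindex(cohort.index)
        if reference.isna().any():
            raise ValueError("cohort and reference must cover identical domain bins")
    if (cohort < 0).any() or (reference < 0).any():
        raise ValueError("counts must be non-negative")
    table = np.vstack([cohort.values, reference.values])
    n = table.sum()
    if n <= 0:
        raise ValueError("totals must be positive")
    row_tot = table.sum(axis=1, keepdims=True)
    col_tot = table.sum(axis=0, keepdims=True)
    expected = row_tot @ col_tot / n
    if (expected == 0).any():
        bad = cohort.index[(expected == 0).any(axis=0)].tolist()
        raise ValueError(
            f"zero expected count in bins {bad}; merge sparse domain bins first"
        )
    with np.errstate(invalid="ignore"):
        resid = (table - expected) / np.sqrt(
            expected * (1 - row_tot / n) * (1 - col_tot / n)
        )
    out = pd.DataFrame(
        {
            "cohort": cohort.astype(int),
            "reference": reference.astype(int),
            "expected_cohort": expected[0],
            "residual": resid[0],
        },
        index=cohort.index,
    )
    out["significant"] = out["residual"].abs() > cutoff
    return out


# ---------------------------------------------------------------------------
# Trend tests


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    jt = 0.0
    for a, b in itertools.combinations(groups, 2):
        less = (a[:, None] < b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        jt += less + 0.5 * ties
    return float(jt)


def _jt_null_moments(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    mean = (n * n - (ns**2).sum()) / 4.0
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    a = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    b = (
        (ns * (ns - 1) * (ns - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * n * (n - 1) * (n - 2))
    )
    c = (ns * (ns - 1)).sum() * (t * (t - 1)).sum() / (8.0 * n * (n - 1))
    return mean, a + b + c


def _distinct_assignments(values: np.ndarray, sizes: Sequence[int]):
    """Yield all distinct splits of ``values`` into ordered groups of the
    given sizes (by index combinations)."""
    def rec2(remaining: np.ndarray, sizes_left: Sequence[int], groups: list):
        if not sizes_left:
            yield groups
            return
        k = sizes_left[0]
        for comb in itertools.combinations(range(len(remaining)), k):
            chosen = remaining[list(comb)]
            rest = np.delete(remaining, list(comb))
            yield from rec2(rest, sizes_left[1:], groups + [chosen])

    yield from rec2(values, list(sizes), [])


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    alternative: str = "increasing",
    exact: Optional[bool] = None,
) -> tuple[float, float]:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    The test is directional by nature; ``alternative`` is "increasing"
    (default), "decreasing", or "two-sided" (doubled smaller tail).
    ``exact=None`` switches to the exact permutation distribution when
    total n <= 12 -- ties at tiny n are handled exactly there, while the
    normal approximation uses the tie-corrected variance and a 0.5
    continuity correction.
    """
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two ordered groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    jt = _jt_statistic(arrays)
    mean, var = _jt_null_moments(arrays)
    n_total = sum(len(a) for a in arrays)
    if exact is None:
        exact = n_total <= 12

    if exact:
        pooled = np.concatenate(arrays)
        sizes = [len(a) for a in arrays]
        ge = le = total = 0
        for split in _distinct_assignments(pooled, sizes):
            total += 1
            s = _jt_statistic(split)
            ge += s >= jt - 1e-9
            le += s <= jt + 1e-9
        if alternative == "increasing":
            return jt, ge / total
        if alternative == "decreasing":
            return jt, le / total
        return jt, min(1.0, 2 * min(ge, le) / total)

    if var <= 0:
        return jt, 1.0
    sd = math.sqrt(var)
    p_inc = float(sps.norm.sf((jt - mean - 0.5) / sd))
    p_dec = float(sps.norm.cdf((jt - mean + 0.5) / sd))
    if alternative == "increasing":
        return jt, p_inc
    if alternative == "decreasing":
        return jt, p_dec
    return jt, min(1.0, 2 * min(p_inc, p_dec))


def linear_by_linear(
    table: np.ndarray | pd.DataFrame,
    row_scores: Optional[Sequence[float]] = None,
    col_scores: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Linear-by-linear association test for an ordinal x ordinal table.

    M^2 = (N - 1) r^2 with r the score correlation; p from chi-square(1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need a 2-D contingency table with >= 2 rows and columns")
    r_scores = np.arange(1, t.shape[0] + 1) if row_scores is None else np.asarray(row_scores, float)
    c_scores = np.arange(1, t.shape[1] + 1) if col_scores is None else np.asarray(col_scores, float)
    n = t.sum()
    pr = t.sum(axis=1) / n
    pc = t.sum(axis=0) / n
    mu_r = (r_scores * pr).sum()
    mu_c = (c_scores * pc).sum()
    cov = ((r_scores[:, None] - mu_r) * (c_scores[None, :] - mu_c) * t).sum() / n
    var_r = ((r_scores - mu_r) ** 2 * pr).sum()
    var_c = ((c_scores - mu_c) ** 2 * pc).sum()
    if var_r == 0 or var_c == 0:
        return 0.0, 1.0
    r = cov / math.sqrt(var_r * var_c)
    m2 = (n - 1) * r * r
    return float(m2), float(sps.chi2.sf(m2, df=1))


def trend_test(
    groups: Sequence[Sequence[float]] | np.ndarray,
    mode: str = "jonckheere",
    **kwargs,
) -> tuple[float, float]:
    """Dispatch to the Jonckheere-Terpstra (ordered samples) or
    linear-by-linear (ordinal contingency table) trend test."""
    if mode == "jonckheere":
        return jonckheere_terpstra(groups, **kwargs)
    if mode == "linear_by_linear":
        return linear_by_linear(groups, **kwargs)
    raise ValueError(f"unknown trend test mode {mode!r}")


# ---------------------------------------------------------------------------
# Survival


def km_median(
    event_age: Sequence[float],
    event: Sequence[bool],
    entry_age: Optional[Sequence[float]] = None,
) -> tuple[Optional[float], pd.DataFrame]:
    """Product-limit median on the age scale, with optional delayed entry.

    Returns (median age or None when not reached, survival curve).  With no
    events the median is simply not reached -- not an error.
    """
    ages = np.asarray(event_age, dtype=float)
    ev = np.asarray(event, dtype=bool)
    entry = None if entry_age is None else np.asarray(entry_age, dtype=float)
    if entry is not None and (ages <= entry).any():
        raise ValueError("event_age must exceed entry_age for every subject")
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=ev, entry=entry)
    curve = kmf.survival_function_.rename(columns={kmf._label: "survival"})
    # smallest age with S <= 0.5; tolerance guards the product-limit
    # rounding exactly at the half-survival step
    below = curve.index[curve["survival"].to_numpy() <= 0.5 + 1e-9]
    if len(below) == 0:
        return None, curve
    return float(below[0]), curve


# ---------------------------------------------------------------------------
# Genotype-phenotype linear models


_GROUP_TERMS = ["PKD1_ID", "PKD1_NT", "PKD2"]


@dataclass
class PhenotypeFit:
    outcome: str
    coefficients: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high
    n_subjects: int
    n_families: int

    @property
    def coef(self) -> pd.Series:
        return self.coefficients["coef"]


def phenotypes_to_frame(subjects: Iterable[SubjectPhenotype]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "family_id": s.family_id,
                "age": s.age,
                "male": 1 if s.sex.value == "male" else 0,
                "group": None if s.genotype_group is None else s.genotype_group.value,
                "httkv": s.httkv,
                "egfr": s.egfr,
                "esrd": s.esrd,
                "esrd_age": s.esrd_age,
            }
        )
    return pd.DataFrame(rows)


def _term_name(raw: str) -> str:
    if raw.startswith("C(group"):
        return raw.split("[T.")[1].rstrip("]")
    if raw == "Intercept":
        return "const"
    return raw


def fit_phenotype_model(
    subjects: Union[pd.DataFrame, Iterable[SubjectPhenotype]],
    outcome: str,
    n_boot: int = 1000,
    seed: int = 0,
    reference: str = "PKD1_PT",
) -> PhenotypeFit:
    """Linear model of log10(htTKV) or eGFR on age, sex and genotype group.

    Point estimates by least squares with the stated reference group;
    uncertainty by resampling whole families with replacement (percentile
    intervals over ``n_boot`` draws; set 0 to skip).  Subjects without the
    outcome or without a detected genotype are excluded.
    """
    if outcome not in ("log10_httkv", "egfr"):
        raise ValueError("outcome must be 'log10_httkv' or 'egfr'")
    df = subjects if isinstance(subjects, pd.DataFrame) else phenotypes_to_frame(subjects)
    df = df[df["group"].notna() & (df["group"] != "NM")].copy()
    if outcome == "log10_httkv":
        df = df[df["httkv"].notna() & (df["httkv"] > 0)]
        df["y"] = np.log10(df["httkv"])
    else:
        df = df[df["egfr"].notna()]
        df["y"] = df["egfr"]
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 genotype groups to fit the model")
    formula = f"y ~ age + male + C(group, Treatment('{reference}'))"

    def fit_once(d: pd.DataFrame) -> pd.Series:
        model = smf.ols(formula, data=d)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            variances = model.exog.var(axis=0)
            bad = [
                model.exog_names[i]
                for i in range(1, model.exog.shape[1])
                if variances[i] == 0
            ]
            raise ValueError(
                f"singular design matrix; collinear term(s): {bad or 'unknown'}"
            )
        res = model.fit()
        return pd.Series(
            {_term_name(k): v for k, v in res.params.items()}, dtype=float
        )

    point = fit_once(df)
    coef_table = pd.DataFrame({"coef": point})
    coef_table["ci_low"] = np.nan
    coef_table["ci_high"] = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fam_ids = df["family_id"].unique()
        grouped = dict(tuple(df.groupby("family_id")))
        draws = []
        for _ in range(n_boot):
            sampled = rng.choice(fam_ids, size=len(fam_ids), replace=True)
            boot = pd.concat([grouped[f] for f in sampled], ignore_index=True)
            if boot["group"].nunique() < df["group"].nunique():
                continue  # degenerate resample; skip
            try:
                draws.append(fit_once(boot))
            except ValueError:
                continue
        if draws:
            boot_df = pd.DataFrame(draws)
            coef_table["ci_low"] = boot_df.quantile(0.025)
            coef_table["ci_high"] = boot_df.quantile(0.975)
    order = ["age", "male", *_GROUP_TERMS, "const"]
    coef_table = coef_table.reindex([t for t in order if t in coef_table.index])
    return PhenotypeFit(
        outcome=outcome,
        coefficients=coef_table,
        n_subjects=len(df),
        n_families=df["family_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# Prognostic scores


def propkd_category(
    subject: SubjectPhenotype, group: GenotypeGroup
) -> tuple[int, str]:
    """PROPKD prognostic score (0-9) and risk category.

    Components: male sex (1), hypertension before 35 (2), first urological
    event before 35 (2), genotype (PKD2 0, PKD1-NT 2, PKD1-PT/ID 4).
    Missing components score 0.  Categories: low 0-3, intermediate 4-6,
    high 7-9.
    """
    group = GenotypeGroup(group)
    if group is GenotypeGroup.NM:
        raise ValueError("PROPKD score is undefined without a detected genotype")
    points = 0
    if subject.sex.value == "male":
        points += 1
    if subject.htn_dx_age is not None and subject.htn_dx_age < 35:
        points += 2
    if subject.urologic_event_age is not None and subject.urologic_event_age < 35:
        points += 2
    points += {
        GenotypeGroup.PKD2: 0,
        GenotypeGroup.PKD1_NT: 2,
        GenotypeGroup.PKD1_PT: 4,
        GenotypeGroup.PKD1_ID: 4,
    }[group]
    if points <= 3:
        category = "low"
    elif points <= 6:
        category = "intermediate"
    else:
        category = "high"
    return points, category


_MAYO_RATES = (0.015, 0.03, 0.045, 0.06)
_MAYO_BASELINE = 150.0  # mL/m at the (floored) age origin
_MAYO_CLASSES = ("1A", "1B", "1C", "1D", "1E")


def mayo_class(httkv: float, age: float, min_age: float = 1.0) -> str:
    """Mayo imaging class (1A-1E) from height-adjusted TKV and age.

    Band boundaries are theoretical growth curves 150 x (1+r)^age for
    r in {1.5, 3, 4.5, 6}%; ages below ``min_age`` are floored to avoid the
    degenerate age-0 limit where all boundaries coincide.
    """
    if httkv <= 0:
        raise ValueError("httkv must be positive")
    if age <= 0:
        raise ValueError("age must be positive")
    a = max(age, min_age)
    for cls, r in zip(_MAYO_CLASSES[:-1], _MAYO_RATES):
        if httkv < _MAYO_BASELINE * (1 + r) ** a:
            return cls
    return _MAYO_CLASSES[-1]


def icc_oneway(scores: Mapping[str, Sequence[float]] | pd.DataFrame) -> float:
    """One-way random-effects ICC(1,1) from the ANOVA decomposition.

    ``scores`` maps each subject to their repeated class scores over
    visits (>= 2 visits for >= 2 subjects).  All-identical input returns 1.
    """
    if isinstance(scores, pd.DataFrame):
        groups = [row.dropna().to_numpy(float) for _, row in scores.iterrows()]
    else:
        groups = [np.asarray(v, dtype=float) for v in scores.values()]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 subjects with >= 2 visits")
    n_groups = len(groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_total = sizes.sum()
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (n_groups - 1)
    ms_within = ss_within / (n_total - n_groups)
    if ms_within == 0 and ms_between == 0:
        return 1.0
    k0 = (n_total - (sizes**2).sum() / n_total) / (n_groups - 1)
    denom = ms_between + (k0 - 1) * ms_within
    if denom == 0:
        return 1.0
    return float((ms_between - ms_within) / denom)
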