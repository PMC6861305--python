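"""Cohort statistics: detection accounting, tabulation, enrichment
residuals, trend tests, survival medians, phenotype regression, prognostic
scores and the intraclass correlation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pkdcohort import (
    Gene,
    GeneratorConfig,
    GenotypeGroup,
    Grade,
    KnownVariantDB,
    SegregationStatus,
    Sex,
    SubjectPhenotype,
    VariantClass,
    VariantRecord,
    detection_summary,
    domain_enrichment,
    fit_phenotype_model,
    generate_cohort,
    generate_phenotypes,
    icc_oneway,
    jonckheere_terpstra,
    km_median,
    linear_by_linear,
    mayo_class,
    novelty_rate,
    propkd_category,
    rate,
    tabulate_class_grade,
)
from pkdcohort.stats import ClassGradeTable, representative_variant


class TestDetection:
    def test_stage_tallies_to_printed_rates(self):
        stages = ["tes"] * 409 + ["sanger_exon1"] * 7 + ["mlpa"] * 7 + ["none"] * 101
        s = detection_summary(stages)
        assert s.n_families == 524
        assert s.n_with_mutation_total == 423
        assert s.rate_tes == 78.1
        assert s.rate_total == 80.7

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            detection_summary([])

    def test_all_undetected(self):
        s = detection_summary(["none"] * 10)
        assert s.rate_tes == 0.0 and s.rate_total == 0.0

    def test_unknown_stage_label(self):
        with pytest.raises(ValueError, match="unknown"):
            detection_summary(["wes"])


def _variant(gene, vclass, grade, pos=100, alt="T"):
    return VariantRecord(chrom="16", pos=pos, ref="A", alt=alt, gene=gene, exon=1,
                         vclass=vclass, grade=grade)


class TestTabulation:
    def test_single_family_single_mutation(self):
        table = tabulate_class_grade(
            {"F1": [_variant(Gene.PKD1, VariantClass.NONSENSE, Grade.DP)]}
        )
        assert table.class_counts.loc["PKD1", "nonsense"] == 1
        assert table.grade_counts.loc["PKD1", "DP"] == 1
        assert table.class_shared.values.sum() == 0
        assert table.total_families == 1

    def test_shared_variant_counted_in_both_families(self):
        v = lambda: _variant(Gene.PKD2, VariantClass.MISSENSE, Grade.LP, pos=7)
        table = tabulate_class_grade({"F1": [v()], "F2": [v()], "F3": []})
        assert table.class_counts.loc["PKD2", "missense"] == 2
        assert table.class_shared.loc["PKD2", "missense"] == 2
        assert table.class_counts.loc["NM", "no_variant"] == 1
        assert table.grade_counts.loc["NM", "NV"] == 1

    def test_non_mutation_grades_count_as_nm_row(self):
        table = tabulate_class_grade(
            {"F1": [_variant(Gene.PKD1, VariantClass.MISSENSE, Grade.I)]}
        )
        assert table.grade_counts.loc["NM", "I"] == 1
        assert table.class_counts.loc["NM", "missense"] == 1

    def test_representative_precedence(self):
        lp = _variant(Gene.PKD2, VariantClass.MISSENSE, Grade.LP, pos=1)
        dp = _variant(Gene.PKD2, VariantClass.NONSENSE, Grade.DP, pos=2)
        assert representative_variant([lp, dp]) is dp
        pkd2 = _variant(Gene.PKD2, VariantClass.NONSENSE, Grade.DP, pos=3)
        pkd1 = _variant(Gene.PKD1, VariantClass.MISSENSE, Grade.DP, pos=4)
        assert representative_variant([pkd2, pkd1]) is pkd1

    def test_modal_class_shares_from_cohort_counts(self):
        cc = pd.DataFrame(
            [[86, 136, 16, 8, 90, 12, 0], [39, 11, 8, 5, 12, 0, 0], [0] * 7],
            index=["PKD1", "PKD2", "NM"],
            columns=[c.value for c in VariantClass],
        )
        table = ClassGradeTable(class_counts=cc, grade_counts=cc * 0)
        assert table.modal_class("PKD1") == ("frameshift", 39)
        assert table.modal_class("PKD2") == ("nonsense", 52)


class TestNovelty:
    def test_known_fraction(self):
        keys = [f"16:{i}:A:G" for i in range(331)]
        db = KnownVariantDB({k: (Grade.DP, "registry") for k in keys[:97]})
        assert novelty_rate(keys, db) == (234, 70.7)

    def test_empty_db_everything_novel(self):
        assert novelty_rate(["a:1:A:G", "a:2:A:G"], KnownVariantDB()) == (2, 100.0)

    def test_all_known(self):
        db = KnownVariantDB({"a:1:A:G": (Grade.DP, "x")})
        assert novelty_rate(["a:1:A:G"], db) == (0, 0.0)


class TestDomainEnrichment:
    def test_hand_computed_2x2_residuals(self):
        # [[10,90],[30,70]]: E11=20, r = -10/sqrt(20*0.5*0.8) = -3.5355
        out = domain_enrichment({"d1": 10, "d2": 90}, {"d1": 30, "d2": 70})
        assert out.loc["d1", "residual"] == pytest.approx(-3.5355, abs=1e-3)
        assert out.loc["d2", "residual"] == pytest.approx(3.5355, abs=1e-3)
        assert out["significant"].tolist() == [True, True]

    def test_2x2_residuals_share_one_magnitude(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            out = domain_enrichment({"x": a, "y": b}, {"x": c, "y": d})
            assert abs(out["residual"].abs().iloc[0] - out["residual"].abs().iloc[1]) < 1e-9

    def test_proportional_vectors_give_zero_residuals(self):
        out = domain_enrichment({"a": 10, "b": 20, "c": 30}, {"a": 20, "b": 40, "c": 60})
        assert np.allclose(out["residual"], 0.0)
        assert not out["significant"].any()

    def test_cutoff_flags_exactly_above(self):
        out = domain_enrichment({"a": 10, "b": 90}, {"a": 30, "b": 70}, cutoff=3.6)
        assert not out["significant"].any()

    def test_zero_expected_cell_requests_bin_merge(self):
        with pytest.raises(ValueError, match="merge"):
            domain_enrichment({"a": 0, "b": 5}, {"a": 0, "b": 7})


class TestTrendTests:
    def test_maximally_ordered_groups(self):
        stat, p = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert stat == 12.0
        # exact permutation p: only the single perfect ordering reaches JT=12
        assert p == pytest.approx(1 / 90, abs=1e-9)

    def test_identical_observations_null(self):
        stat, p = jonckheere_terpstra([[5, 5], [5, 5], [5, 5]], exact=False)
        assert p == 1.0

    def test_two_groups_reduce_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(size=8), rng.normal(1.0, size=9)
        stat, p = jonckheere_terpstra([g1, g2], exact=False)
        u = sps.mannwhitneyu(g2, g1, alternative="two-sided")
        assert stat == pytest.approx(u.statistic)
        u1 = sps.mannwhitneyu(g1, g2, alternative="less", method="asymptotic")
        assert p == pytest.approx(u1.pvalue, abs=1e-9)

    def test_normal_approximation_tracks_exact_p(self):
        """|p_norm - p_exact| <= 0.02 for continuous small samples (ties at
        tiny n are routed to the exact path by default)."""
        rng = np.random.default_rng(6)
        for trial in range(15):
            sizes = rng.choice([2, 3, 4], size=3)
            if sizes.sum() > 12:
                continue
            vals = rng.normal(size=sizes.sum())
            groups = np.split(vals, np.cumsum(sizes)[:-1])
            _, p_exact = jonckheere_terpstra(groups, exact=True)
            _, p_norm = jonckheere_terpstra(groups, exact=False)
            assert abs(p_exact - p_norm) <= 0.02, (sizes, vals)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2, 3]])

    def test_linear_by_linear_matches_expanded_correlation(self):
        table = np.array([[20, 10, 5], [10, 15, 10], [5, 10, 20]])
        stat, p = linear_by_linear(table)
        rows, cols = [], []
        for i in range(3):
            for j in range(3):
                rows += [i + 1] * table[i, j]
                cols += [j + 1] * table[i, j]
        r = np.corrcoef(rows, cols)[0, 1]
        expected = (table.sum() - 1) * r**2
        assert stat == pytest.approx(expected)
        assert p == pytest.approx(sps.chi2.sf(expected, 1))


class TestKaplanMeier:
    def test_uncensored_sample_gives_empirical_median(self):
        median, _ = km_median([50, 60, 70], [True, True, True])
        assert median == 60

    def test_all_censored_not_reached(self):
        median, _ = km_median([50, 60], [False, False])
        assert median is None

    def test_km_equals_empirical_median_without_censoring(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(1, 40))
            ages = np.round(rng.uniform(30, 90, size=n), 1)
            median, _ = km_median(ages, np.ones(n, bool))
            srt = np.sort(ages)
            # smallest value with F >= 0.5
            empirical = srt[int(np.ceil(n / 2)) - 1]
            assert median == pytest.approx(empirical)

    def test_delayed_entry_validates_ordering(self):
        with pytest.raises(ValueError):
            km_median([50, 60], [True, True], entry_age=[55, 30])
        median, _ = km_median([50, 60, 70], [True] * 3, entry_age=[40, 41, 42])
        assert median == 60

    def test_synthetic_pkd2_arm_recovers_generator_median(self):
        from pkdcohort import sample_esrd_ages
        cfg = GeneratorConfig(seed=12)
        rng = np.random.default_rng(12)
        ages = sample_esrd_ages(GenotypeGroup.PKD2, 500, cfg, rng)
        median, _ = km_median(ages, np.ones(500, bool))
        assert median == pytest.approx(72.9, abs=1.5)


def _zero_noise_config(seed=0, **kw):
    return GeneratorConfig(
        seed=seed,
        nm_fraction=0.0,
        httkv_residual_sd=0.0,
        httkv_family_sd=0.0,
        egfr_residual_sd=0.0,
        egfr_family_sd=0.0,
        with_depth=False,
        **kw,
    )


class TestPhenotypeModel:
    def test_zero_noise_recovers_truth_exactly(self):
        cfg = _zero_noise_config(seed=21, n_subjects_target=250)
        bundle = generate_cohort(cfg)
        subjects = [s for s in bundle.phenotypes if not s.esrd]
        fit = fit_phenotype_model(subjects, "log10_httkv", n_boot=0)
        for term, truth in cfg.httkv_coefs.items():
            assert fit.coef[term] == pytest.approx(truth, abs=1e-8), term
        fit = fit_phenotype_model(subjects, "egfr", n_boot=0)
        for term, truth in cfg.egfr_coefs.items():
            assert fit.coef[term] == pytest.approx(truth, abs=1e-6), term

    def test_cluster_bootstrap_brackets_point_estimate(self):
        bundle = generate_cohort(
            GeneratorConfig(seed=22, n_subjects_target=200, nm_fraction=0.0,
                            with_depth=False)
        )
        fit = fit_phenotype_model(bundle.phenotypes, "log10_httkv", n_boot=60, seed=5)
        row = fit.coefficients.loc["age"]
        assert row["ci_low"] < row["coef"] < row["ci_high"]

    def test_singular_design_names_collinear_term(self):
        subjects = [
            SubjectPhenotype(subject_id=f"s{i}", family_id=f"f{i}", sex=Sex.FEMALE,
                             age=40 + i, httkv=500.0,
                             genotype_group=GenotypeGroup.PKD1_PT if i % 2 else GenotypeGroup.PKD2)
            for i in range(12)
        ]
        with pytest.raises(ValueError, match="male"):
            fit_phenotype_model(subjects, "log10_httkv", n_boot=0)


class TestPrognosticScores:
    def test_propkd_examples(self):
        male_early_htn = SubjectPhenotype(subject_id="a", family_id="f", sex=Sex.MALE,
                                          age=50, htn=True, htn_dx_age=30, httkv=800.0)
        assert propkd_category(male_early_htn, GenotypeGroup.PKD1_PT) == (7, "high")
        quiet_female = SubjectPhenotype(subject_id="b", family_id="f", sex=Sex.FEMALE,
                                        age=50, httkv=400.0)
        assert propkd_category(quiet_female, GenotypeGroup.PKD2) == (0, "low")
        quiet_male = SubjectPhenotype(subject_id="c", family_id="f", sex=Sex.MALE,
                                      age=50, httkv=400.0)
        assert propkd_category(quiet_male, GenotypeGroup.PKD1_NT) == (3, "low")

    def test_propkd_rejects_nm(self):
        s = SubjectPhenotype(subject_id="a", family_id="f", sex=Sex.MALE, age=40)
        with pytest.raises(ValueError):
            propkd_category(s, GenotypeGroup.NM)

    def test_mayo_matches_boundary_table_oracle(self):
        age = 45.0
        bounds = [150 * (1 + r) ** age for r in (0.015, 0.03, 0.045, 0.06)]
        for httkv in (100, 250, 300, 450, 600, 900, 1500, 3000):
            k = sum(httkv >= b for b in bounds)
            assert mayo_class(httkv, age) == ("1A", "1B", "1C", "1D", "1E")[k]

    def test_mayo_monotone_in_httkv(self):
        order = ["1A", "1B", "1C", "1D", "1E"]
        prev = 0
        for httkv in np.linspace(50, 5000, 60):
            k = order.index(mayo_class(float(httkv), 45.0))
            assert k >= prev
            prev = k

    def test_mayo_age_floor_guard(self):
        assert mayo_class(200.0, 0.01) == "1E"  # floored, not degenerate
        with pytest.raises(ValueError):
            mayo_class(200.0, 0.0)


class TestICC:
    def test_perfect_repeats(self):
        scores = {f"s{i}": [i, i, i] for i in range(10)}
        assert icc_oneway(scores) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(13)
        scores = {f"s{i}": rng.normal(size=3) for i in range(400)}
        assert abs(icc_oneway(scores)) < 0.08

    def test_recovers_generator_variance_ratio(self):
        """Between/total variance 0.84 is recovered within +/-0.03 at n=500."""
        rng = np.random.default_rng(14)
        scores = {}
        for i in range(500):
            subj = rng.normal(0, np.sqrt(0.84))
            scores[f"s{i}"] = subj + rng.normal(0, np.sqrt(0.16), size=3)
        assert icc_oneway(scores) == pytest.approx(0.84, abs=0.03)


def test_rate_uses_round_half_up():
    assert rate(79, 80) == 98.8
    assert rate(70, 74) == 94.6
    assert rate(1, 16) == 6.3  # 6.25 rounds up, not to even
    assert rate(371, 630, decimals=0) == 59
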