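"""Generator contracts: determinism, Mendelian transmission, the study-mix
probabilities, and closed-form phenotype/Weibull checks."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from pkdcohort import (
    Affection,
    Carrier,
    GeneratorConfig,
    GenotypeGroup,
    Gene,
    VariantClass,
    annotate_consequence,
    build_toy_transcript,
    generate_cohort,
    generate_phenotypes,
    load_bundle,
    sample_esrd_ages,
    write_bundle,
)
from pkdcohort.simulate import weibull_scale_for_median


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = dict(seed=77, n_families=30)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_bundle(generate_cohort(GeneratorConfig(**cfg)), d1)
    write_bundle(generate_cohort(GeneratorConfig(**cfg)), d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_bundle_round_trips_through_disk(tmp_path, small_bundle):
    write_bundle(small_bundle, tmp_path / "c")
    back = load_bundle(tmp_path / "c")
    assert len(back.families) == len(small_bundle.families)
    assert set(back.variants) == set(small_bundle.variants)
    assert back.truth["families"] == small_bundle.truth["families"]
    assert back.sanger_exon1 == small_bundle.sanger_exon1
    assert len(back.known_db) == len(small_bundle.known_db)


def test_mendelian_consistency(full_bundle):
    """Every typed carrier child with two typed parents has a carrier parent."""
    checked = 0
    for fam in full_bundle.families:
        by_id = {m.individual_id: m for m in fam.members}
        for m in fam.members:
            if m.father_id is None or m.mother_id is None:
                continue
            f, mo = by_id[m.father_id], by_id[m.mother_id]
            for key, status in m.carrier.items():
                if status is not Carrier.CARRIER:
                    continue
                fs, ms = f.carrier.get(key), mo.carrier.get(key)
                if fs is None or ms is None:
                    continue  # untyped parent: cannot adjudicate
                assert Carrier.CARRIER in (fs, ms), (fam.family_id, key)
                checked += 1
    assert checked > 100


def test_group_mix_matches_study_probabilities(full_bundle):
    truth = full_bundle.truth["families"]
    groups = [f["group"] for f in truth.values()]
    n = len(groups)
    n_nm = groups.count("NM")
    # NM fraction within binomial 99% bounds of 101/524
    p_nm = 101 / 524
    assert abs(n_nm - n * p_nm) < 3 * math.sqrt(n * p_nm * (1 - p_nm))
    detected = [g for g in groups if g != "NM"]
    for g, p in zip(("PKD1_PT", "PKD1_ID", "PKD1_NT", "PKD2"), (0.59, 0.03, 0.19, 0.19)):
        k = detected.count(g)
        assert abs(k - len(detected) * p) < 3 * math.sqrt(len(detected) * p * (1 - p)), g


def test_causal_class_is_consistent_with_group(full_bundle):
    group_classes = {
        "PKD1_PT": {"nonsense", "frameshift", "typical_splicing", "large_del_dup"},
        "PKD1_ID": {"inframe_indel"},
        "PKD1_NT": {"missense"},
        "PKD2": {"nonsense", "frameshift", "typical_splicing", "large_del_dup", "missense"},
        "NM": {None},
    }
    for f in full_bundle.truth["families"].values():
        assert f["causal_class"] in group_classes[f["group"]]


def test_causal_records_classify_to_their_truth_class(full_bundle):
    """Variants synthesised for a class genuinely realise that class when
    classified from sequence."""
    n = 0
    for fid, f in full_bundle.truth["families"].items():
        key = f["causal_key"]
        if key is None:
            continue
        rec = full_bundle.variants[key]
        tx = full_bundle.transcripts[rec.gene.value]
        got = annotate_consequence(rec, tx)
        assert got.value == f["causal_class"], fid
        n += 1
    assert n > 300


def test_degenerate_all_truncating_config():
    cfg = GeneratorConfig(seed=5, n_families=20, nm_fraction=0.0,
                          genotype_group_probs=(1.0, 0.0, 0.0, 0.0),
                          pkd1_truncating_class_probs=(1.0, 0.0, 0.0, 0.0),
                          with_depth=False)
    bundle = generate_cohort(cfg)
    for f in bundle.truth["families"].values():
        assert f["group"] == "PKD1_PT" and f["causal_class"] == "nonsense"


@pytest.mark.parametrize(
    "kw",
    [
        dict(nm_fraction=1.0),  # nonzero group probs left with no families
        dict(genotype_group_probs=(0.5, 0.5, 0.5, 0.5)),
        dict(httkv_residual_sd=-1.0),
        dict(nm_fraction=1.5),
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        GeneratorConfig(seed=1, **kw)


class TestPhenotypeGeneration:
    def test_closed_form_zero_noise(self):
        """Female, 50 y, PKD1-PT, no noise: log10(htTKV) = 2.378 + 0.6."""
        from pkdcohort.models import Family, PedigreeIndividual, Sex

        cfg = GeneratorConfig(seed=1, httkv_residual_sd=0, httkv_family_sd=0,
                              egfr_residual_sd=0, egfr_family_sd=0)
        rng = np.random.default_rng(0)
        member = PedigreeIndividual(family_id="F", individual_id="F_P",
                                    sex=Sex.FEMALE, affected=Affection.AFFECTED, age=50.0)
        fam = Family(family_id="F", members=[member])
        (pt,) = generate_phenotypes([fam], {"F": GenotypeGroup.PKD1_PT}, cfg, rng)
        assert math.log10(pt.httkv) == pytest.approx(2.378 + 0.012 * 50, abs=1e-9)
        rng = np.random.default_rng(0)
        (p2,) = generate_phenotypes([fam], {"F": GenotypeGroup.PKD2}, cfg, rng)
        if not pt.esrd and not p2.esrd:
            assert p2.egfr - pt.egfr == pytest.approx(18.476, abs=1e-9)
            assert math.log10(p2.httkv) - math.log10(pt.httkv) == pytest.approx(
                -0.161, abs=1e-9)

    def test_weibull_median_closed_form(self):
        """1e5 draws of the PKD2 clock: sample median within 72.9 +/- 0.5."""
        cfg = GeneratorConfig(seed=2)
        rng = np.random.default_rng(2)
        draws = sample_esrd_ages("PKD2", 100_000, cfg, rng)
        assert np.median(draws) == pytest.approx(72.9, abs=0.5)
        scale = weibull_scale_for_median(72.9, 6.0)
        assert scale * math.log(2) ** (1 / 6.0) == pytest.approx(72.9)

    def test_esrd_subjects_record_egfr_15(self, full_bundle):
        esrd = [s for s in full_bundle.phenotypes if s.esrd]
        assert esrd and all(s.egfr == 15.0 for s in esrd)
        assert all(s.esrd_age is not None and s.esrd_age <= s.age for s in esrd)


class TestDepthGeneration:
    def test_noise_free_config_gives_exact_unit_ratios(self):
        from pkdcohort import generate_depth_matrix, normalize_depth
        cfg = GeneratorConfig(seed=3, depth_nb_size=math.inf,
                              library_factor_sd=0.0, capture_factor_sd=0.0)
        rng = np.random.default_rng(3)
        txs = {Gene.PKD1: build_toy_transcript(Gene.PKD1, rng),
               Gene.PKD2: build_toy_transcript(Gene.PKD2, rng)}
        m = generate_depth_matrix(["a", "b", "c"], txs, [], cfg, rng)
        assert (normalize_depth(m).values == 1.0).all()

    def test_default_noise_keeps_ratios_near_one(self):
        from pkdcohort import generate_depth_matrix, normalize_depth
        cfg = GeneratorConfig(seed=4)
        rng = np.random.default_rng(4)
        txs = {Gene.PKD1: build_toy_transcript(Gene.PKD1, rng),
               Gene.PKD2: build_toy_transcript(Gene.PKD2, rng)}
        m = generate_depth_matrix([f"s{i}" for i in range(20)], txs, [], cfg, rng)
        ratios = normalize_depth(m)
        assert (np.abs(ratios.values - 1.0) < 0.3).all()

    def test_injected_truth_events_are_recoverable(self, full_bundle):
        from pkdcohort import call_cnv, normalize_depth, CNVType
        ratios = normalize_depth(full_bundle.depth)
        calls = call_cnv(ratios)
        for ev in full_bundle.truth["cnv_events"]:
            if not ev["in_depth"]:
                continue
            hit = any(
                c.sample_id == ev["sample_id"]
                and c.gene.value == ev["gene"]
                and c.call.value == ev["type"]
                and c.exon_start <= ev["exon_end"]
                and ev["exon_start"] <= c.exon_end
                for c in calls
            )
            assert hit, ev


def test_subject_target_reaches_requested_size():
    bundle = generate_cohort(GeneratorConfig(seed=6, n_subjects_target=150,
                                             with_depth=False))
    assert len(bundle.phenotypes) >= 150
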