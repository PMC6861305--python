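"""Generate a synthetic ADPKD family cohort and run the whole pipeline.

The generator emits variants, pedigrees, exon depths and phenotypes under
the study's default mix (59/3/19/19% genotype groups among detected
families, ~19% with no detectable mutation); the pipeline then recovers
mutations stage by stage (sequencing, exon-1 Sanger rescue, MLPA rescue).
"""
from collections import Counter

from pkdcohort import GeneratorConfig, generate_cohort, run_pipeline

bundle = generate_cohort(GeneratorConfig(seed=3))
result = run_pipeline(bundle)
det = result.detection

print(f"families: {det.n_families}, phenotyped subjects: {len(bundle.phenotypes)}")
print(f"detection rate, sequencing alone: {det.rate_tes}%")
print(
    f"detection rate with rescues:       {det.rate_total}% "
    f"({det.n_with_mutation_total}/{det.n_families}; "
    f"+{det.n_rescued_sanger_exon1} exon-1 Sanger, +{det.n_rescued_mlpa} MLPA)"
)
print(f"novel mutations: {result.novelty_pct}%")
groups = Counter(r.genotype_group.value for r in result.families)
print("genotype groups:", dict(groups))
print()
print("A detection rate near 80% and a PKD1-PT-dominated group mix mirror")
print("what a targeted-panel ADPKD study of this design reports.")
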