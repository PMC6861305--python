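# Methods

This note documents the models behind `pkdcohort`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic cohorts
can and cannot demonstrate.

## Variant prioritization

A record survives when it is exonic or canonical-splicing, not a
synonymous SNV, rare, and passes three quality gates. Boundary semantics
follow the stated rules exactly: population allele frequency strictly
greater than 0.01 is discarded (AF = 0.01 survives); variant quality
< 20 and genotype quality < 30 are excluded; mapping quality must be
strictly greater than 30. Two conventions need stating because missing
data are common in panel annotations:

* An **absent population frequency is treated as rare**. Novel variants
  have no frequency evidence, and absence of evidence is not evidence of
  commonness; the alternative (dropping unannotated variants) would
  discard most genuinely novel pathogenic alleles.
* A **dbSNP identifier alone never excludes** a variant — many
  established pathogenic alleles carry rs numbers. Only the frequency
  rule excludes.

The audit lists every violated rule, not the first hit, so a filter run
can be reviewed retrospectively. The filter is idempotent, permutation
equivariant, and monotone in its thresholds; the test suite pins all
three properties.

## Consequence classification

`TranscriptModel` is a minimal spliced-transcript description (ordered
exon intervals, CDS bounds, coding-strand sequence; both strands are
supported, with plus-strand VCF alleles complemented on minus-strand
transcripts). Classification is local:

* SNVs are judged by their own codon: same residue → synonymous marker
  (consumed only by the filter), new stop → nonsense, otherwise
  missense. The same-residue check precedes the stop check so that
  stop-to-stop changes (e.g. TAA→TGA) classify as synonymous.
* Indel length modulo 3 separates frameshift from in-frame; the in-frame
  amino-acid length is `|Δ|/3`.
* Positions at the intronic ±1/±2 of any internal exon boundary are
  *typical splicing*; deeper intronic positions are outside the
  exonic/splicing scope by construction.
* Symbolic alleles (`<DEL>`, `<DUP>`) and literal deletions spanning a
  whole exon are large deletion/duplication events.

The classifier is verified against an independent oracle that applies
the edit to the CDS, translates both sequences with Biopython, and
classifies from the protein diff — exhaustively over all SNVs of a toy
transcript and systematically over ≤ 6-bp indels.

## Pathogenicity grading

Grades DP > HLP > LP > I > LN (plus NV), with DP/HLP/LP counted as
mutations. The decision tree, evaluated in order:

1. truncating class (nonsense, frameshift, typical splicing, large
   del/dup) **or** registry-established DP → **DP**;
2. registry HLP → **HLP**; registry LP → **LP** (only *novel* LP
   variants are re-arbitrated by segregation);
3. novel damaging missense/in-frame — segregation positive → **HLP**,
   negative → **LN**, otherwise → **LP**;
4. novel non-damaging missense/in-frame — segregation negative →
   **LN**, otherwise → **I**;
5. no variant → **NV**.

*Damaging* means at least two of: SIFT ≤ 0.05, PolyPhen-2 (HumDiv)
damaging, GERP++ ≥ 4 (boundaries inclusive). An absent score is a
non-hit rather than a blocker, so grading always completes. The residual
cells of step 4 (the LN/I split for non-damaging novel variants) are a
reconstruction — the source workflow defers their exact definitions to
supplementary material — chosen so that negative segregation is the only
way to declare a variant likely neutral without in-silico support.
The tree is a total function; tests enumerate the full input space
against an independently written flat table and check that segregation
evidence moves grades monotonically with DP absorbing.

## Segregation

A relative is *informative* when typed, not the proband, and of known
affection — except unaffected carriers at or below the penetrance age
(default 40 y), who are uninformative rather than discordant: ADPKD
imaging penetrance is near-complete only by mid-adulthood, so a young
unaffected carrier is expected under the causal hypothesis. An
unaffected carrier of unknown age is likewise uninformative (the rule
cannot be applied). Any typed affected non-carrier or over-age
unaffected carrier is discordant → negative; no discordance with at
least `min_informative` (default 1) informative relatives → positive;
otherwise inconclusive. The workflow applies segregation only to novel
LP variants, mirroring practice; the operation itself is
variant-agnostic.

## Depth-ratio CNV screen

Two-stage median normalization: each sample's exon depths are divided by
the sample median across exons (library size), then each exon's values
by the cohort median at that exon (capture efficiency). Medians resist
the CNV's own signal, and the result is exactly invariant to per-sample
scalar depth factors. A diploid background sits at ratio 1; calling
thresholds 0.65 / 1.35 are midway between diploid and single-copy (0.5)
/ three-copy (1.5) expectations. Maximal runs of consecutive
same-direction exons merge into one call (verified against a brute-force
O(n²) interval scan); single-exon calls are flagged as needing
orthogonal confirmation, and MLPA reconciliation marks confirmations,
depth-only calls and MLPA-only events (depth misses) both ways. The
screen requires ≥ 3 samples because the cohort reference is a median.

At the generator's noise level (ratio CV ≈ 0.08) the screen detects
every simulated ≥ 3-exon heterozygous deletion at noise sd ≤ 0.1 across
200 seeded replicates and produces ≤ 1 spurious call per 100 diploid
samples. No GC-bias correction is attempted: GC-driven dropout (the
*PKD1* exon-1 problem) is handled as a workflow fallback (Sanger
rescue), not as a depth model.

## Cohort statistics

* **Rates** use round-half-up (1 decimal for percentages, integers for
  class shares), matching how such tables are printed.
* **Detection accounting** is per family, by the first assay stage that
  yielded a mutation (sequencing, exon-1 Sanger, MLPA); a family counts
  once regardless of its number of variants. Families with several
  graded mutations resolve to one representative: highest grade, then
  *PKD1* over *PKD2*, then the most truncating class — a rule the
  workflow needs but the source leaves unstated.
* **Domain enrichment** uses adjusted standardized residuals of the
  2 × k cohort-vs-reference table,
  `r = (O − E)/√(E(1 − row/N)(1 − col/N))`, flagged at |r| > 2.58
  (α ≈ 0.01 two-sided). Zero expected cells raise an error instructing
  bin merging. In a 2 × 2 table all four residuals share one magnitude
  (algebraic identity, tested).
* **Jonckheere–Terpstra** is implemented as the sum of pairwise
  Mann-Whitney counts with 0.5 per tie. The test is directional by
  nature (ordered alternative); the default is one-sided increasing,
  with decreasing and doubled two-sided options. Total n ≤ 12 switches
  to the exact permutation distribution over distinct group
  assignments, which also handles ties exactly; the normal
  approximation uses the tie-corrected variance with a 0.5 continuity
  correction and agrees with the exact p within 0.02 on continuous data
  at these sizes. Linear-by-linear association uses M² = (N−1)r² on
  integer scores with a χ²(1) reference.
* **Kaplan–Meier** medians are computed on the age scale via lifelines
  with optional delayed entry (both entry conventions are provided
  because the source does not state which was used). The median is the
  smallest age with S(t) ≤ 0.5, extracted with a 1e-9 tolerance because
  the product-limit estimator can land on 0.5 up to floating-point
  rounding; with no censoring this equals the empirical median
  (property-tested). No events → "not reached", not an error.
* **Genotype–phenotype models** are least-squares fits of log₁₀(htTKV)
  or eGFR on age + male + genotype group (PKD1-PT reference).
  Uncertainty comes from resampling whole families with replacement
  (default 1000 draws, seeded percentile intervals) — a cluster
  bootstrap standing in for the original multilevel/sandwich machinery;
  fixed-effect point estimates are what parameter recovery tests. The
  htTKV model is log base 10: the printed intercept 2.378 then
  corresponds to ≈ 239 mL/m at covariate zero, consistent with the
  observed medians (natural log would imply ≈ 11 mL/m). eGFR fits
  exclude subjects on renal replacement, whose recorded eGFR of 15 is a
  bookkeeping convention rather than a measurement; because ESRD onset
  is driven by an age clock independent of the eGFR residual, this
  exclusion does not bias the coefficients.
* **PROPKD** components: male 1, hypertension before 35 y 2, first
  urological event before 35 y 2, genotype 0/2/4 (PKD2 / PKD1-NT /
  PKD1-PT or -ID); categories low 0–3, intermediate 4–6, high 7–9.
  Missing components score 0.
* **Mayo imaging class** boundaries are the theoretical growth curves
  150 × (1+r)^age for r ∈ {1.5, 3, 4.5, 6}% (externally sourced
  formula); ages are floored at 1 y to avoid the degenerate age-0 limit
  where all boundaries coincide.
* **ICC** is the one-way random-effects ICC(1,1) from the ANOVA
  decomposition, with the unbalanced-design group-size correction and a
  guarded return of 1 for all-identical input.

## Synthetic cohort generator

The generator's defaults are the study conditions; everything flows from
one mandatory seed through a single `numpy` Generator.

* **Genotype mix**: 101/524 of families carry no detectable mutation
  (NM); detected families are PKD1-PT/ID/NT/PKD2 at 59/3/19/19 %.
  Class mixes within gene follow the cohort tabulation (PKD1 truncating
  classes 86:136:16:8; PKD2 39:11:8:5:12 over five classes).
* **Variants are real edits** on toy transcripts (46 exons for *PKD1*
  on chr16, 15 for *PKD2* on chr4, 12 codons per exon, codon-aligned
  boundaries), synthesised so the consequence classifier genuinely
  reproduces the intended class from sequence. Known-registry status is
  assigned to 97/331 of causal variants (DP/HLP/LP at 0.6/0.25/0.15 —
  the registry split is not printed; chosen once). Benign decoys
  (Poisson mean 2 per family) exercise the filter and the LN/I paths:
  benign missense, synonymous, common (AF > 1 %), low-quality and deep
  intronic kinds.
* **In-silico scores** conditional on pathogenicity: damaging variants
  draw SIFT ~ Beta(0.5, 20), PolyPhen damaging w.p. 0.9,
  GERP ~ N(5.5, 1); benign draw Beta(2, 2), 0.1, N(1.5, 1.5). Each
  score is missing w.p. 0.05, so a realistic minority of causal
  missense variants fail the 2-of-3 rule and stay indeterminate — the
  honest reason simulated detection sits a few points below the
  all-stages rate.
* **Pedigrees**: proband plus parents w.p. 0.55 and Poisson(0.8)
  siblings; each carried variant enters through one transmitting parent
  and siblings inherit w.p. 1/2 (Mendelian consistency is checked
  exhaustively in tests); relatives are typed w.p. 0.8; carriers are
  affected once past the penetrance age (40 y). Ages are N(46, 13)
  truncated to 18–85; male probability 0.48.
* **Capture realism knobs**: *PKD1* exon-1 SNVs are missed by
  sequencing (GC dropout) and surface in the Sanger-rescue table; large
  deletions/duplications appear in the depth matrix only w.p. 0.5
  (mirroring the reported 3-of-6 depth detection) but always in the
  MLPA table.
* **Phenotypes**: log₁₀(htTKV) = 2.378 + 0.012·age + 0.102·male +
  effect(group) + family intercept + noise, with group effects
  −0.033/−0.153/−0.161 (ID/NT/PKD2 vs PT), residual sd 0.2 and family
  intercept sd 0.1; eGFR analogously with 148.405 − 1.840·age −
  6.535·male + 2.668/7.278/18.476, residual sd 15 and family sd 8
  (clustering magnitudes are not printed; chosen to make the family
  effect detectable without overwhelming the fixed effects, ICC ≈ 0.2).
  NM subjects reuse the mildest (PKD2) effect, consistent with their
  described phenotype. ESRD ages follow Weibull clocks with shape 6 and
  scale solved so the medians are exactly 63.5/72.7/68.8/72.9 y
  (PT/ID/NT/PKD2; NM uses the PKD2 clock); subjects past their clock
  have eGFR recorded as 15. Non-ESRD eGFR values are left exactly as
  drawn (they can be implausibly low at high ages) because any flooring
  would bias coefficient recovery.
* **Depth**: negative binomial with mean 1000, size 200 (ratio
  CV ≈ 0.08), log-normal per-sample library and per-exon capture
  factors (sd 0.2); injected events multiply depth by 0.5 or 1.5. An
  infinite size gives the exact noise-free matrix.

### What the synthetic cohorts do and do not show

Truth files make every stage scorable: filter audits against decoy
kinds, classes and grades against the causal labels, CNV calls against
injected events, recovered coefficients and medians against generator
truth. What passing proves is that the *machinery* is correct under the
stated generating model. It does not validate the biology: there is no
pseudogene homology or sequence-level read simulation (mapping quality
enters only as a field), no GC model, no real linkage structure beyond
nuclear families, and phenotype noise is Gaussian by construction. The
cohort-level biological findings that require the real cohort and the
reference mutation registry (the frailty hazard ratio for PKD2, the
domain residual 2.8 against the registry) are deliberately out of
scope; the corresponding formulas are instead pinned against closed-form
oracles.

## Problem sizes

The test suite regenerates cohorts of 60–524 families and recovery runs
of 50 replicates × ~600 subjects; the acceptance script uses the same
sizes. These match the study scale while keeping a full run on one CPU
in well under a minute for the suite's simulation parts.

## Known limitations

* Grading follows one representative variant per family; compound
  genotypes (two mutations in one family) are resolved by precedence,
  not modelled jointly.
* The CNV screen has no breakpoint resolution and no GC correction;
  single-exon events are only as good as their MLPA confirmation.
* The cluster bootstrap gives percentile intervals, not REML variance
  components; the family random effect is never itself estimated.
* PED files carry age in a non-standard optional 7th column because the
  segregation penetrance rule needs relative ages.
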