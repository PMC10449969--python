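# Methods

## Setting and model

The package analyses a small case cohort (n cases, default 50) with full
per-sample genotypes, read support and functional annotations, against a
population control cohort (N individuals, default 125,748 — the size of the
gnomAD v2.1.1 exome set) known only through per-site summary statistics:
allele count AC, allele number AN and homozygote count nhom. Nothing at the
individual level is assumed about controls; every control-side quantity is
an approximation built from those three numbers. All variants are assumed
normalized, biallelic and left-aligned before loading; the reader validates
this (multiallelic records are a hard error) but does not normalize.

### Variant prioritization

Variant-level filters (an SNV deleteriousness consensus with a strict
MAF < 0.001 rule, a MAF-only rule for indels), a per-call allele-ratio QC,
and a cohort-level recurrence filter are pure predicates applied as a
cascade. Thresholds follow their conventional printed forms exactly:
AR windows inclusive (het in [0.35, 0.65], hom ≥ 0.9), MAF strictly below
threshold, recurrence at most 5 distinct carrier individuals (not alleles).
The categorical "deleterious" calls are encoded numerically where only a
score is available: SIFT ≤ 0.05 and PolyPhen2 ≥ 0.909 (the HumDiv
"probably damaging" cutoff). Two conservative conventions matter:

- a **missing MAF is treated as 0** — a variant absent from the reference
  populations is maximally rare and must pass rarity filters;
- a **missing functional score fails** any consensus that requires it, so
  unannotated noise cannot flood the collapsed gene list.

Because the predicates commute, cascade order only determines how removed
calls are attributed in the attrition ledger (functional/MAF, then allele
ratio, then recurrence); the ledger always sums to the input call count.
The allele-ratio QC is applied to indel calls as well by default — it is a
read-support check, not a consequence-type check — with
`apply_ar_to_indels=False` available to restrict it to SNVs.

### Overrepresentation

The ORA is the standard Fisher exact test on the 2×2 of list/term
membership over an explicit background universe, two-sided by default so
that depleted processes are reported alongside enriched ones (direction is
the sign of k − nK/M; ties count as "under"). The background is always
explicit — either a supplied gene list or the union of the collection's
terms — because significance is meaningless relative to an unstated
universe. BH adjustment defaults to the number of terms tested;
`bh_adjust` also supports adjusting a subset against a larger declared
family (`m_total` ≥ number of p-values).

### Burden test

Per gene, the qualifying-variant set ("SNP file") contains every variant
passing the variant-level rules (SNV, SIFT ≤ 0.05, PolyPhen ≥ 0.8,
MAF < 0.01). The depth rule (carrier depth > 10, strict) is per carrier
call: it controls which case carriers are counted, not whether the site is
in the SNP file. A qualifying site with no depth-passing carrier still
contributes its control allele count; a gene is tested only when at least
one carrier remains. This distinction is load-bearing: summing control AC
only over case-ascertained sites conditions the control side on the case
outcome and makes singleton genes anti-conservative (a gene tested because
of its single carrier has p ≈ P(X ≥ 1), which hovers at the rejection
threshold by construction). With catalog-level control sums, the one-sided
test is conservative, as the null-calibration suite verifies.

Dominant-model case carriers are individuals with any qualifying call
(het + hom). The control side assumes each of the summed alleles sits in a
distinct individual, capped at N — the most conservative mapping from
allele counts to carrier counts, and the one consistent with control
heterozygote counts equalling total AC in summary data at these
frequencies. The test is one-sided (excess in cases), P(X ≥ a) under the
hypergeometric with fixed margins; a two-sided alternative exists on the
ORA surface.

Recessive-model case carriers are homozygotes plus samples with ≥ 2
distinct het qualifying sites in the gene. Phase is unknown, so the
compound-het count is an upper bound on true biallelic carriers and is
labelled as putative throughout. The control side is genuinely
under-determined by summary statistics; two strategies are implemented and
must be chosen explicitly:

- `reported_hom` (default): control biallelic carriers = Σ nhom. This
  ignores control compound hets entirely and is therefore
  anti-conservative; it is the construction most directly supported by the
  summary fields.
- `expected_biallelic`: N · (1 − Π(1 − f_i))², the probability under site
  independence (no linkage) that both haplotypes of a control individual
  carry some qualifying allele. It includes homozygotes and never falls
  below `reported_hom` at positive frequencies (a tested invariant).

No recessive-model result is validated against external reference values:
the reference screen's printed recessive p-values are not reproducible from
its printed counts under either construction, so the recessive test is
exercised by simulation and invariants only.

BH families are per model, over genes with ≥ 1 qualifying case carrier
(restricted further when a gene subset — e.g. the top enriched term — is
given). `implied_bh_m` diagnoses the family size implied by a table of
(p, FDR) pairs via max over unclipped rows of fdr·rank/p; on the reference
dominant table it yields ≈ 264, an order of magnitude above the 49 printed
rows, quantifying how much larger the original testing family was than the
reported one.

## Synthetic-data generator

`simulate_cohort` draws, per site, case carriers as Bernoulli with
probability min(1, multiplier · c) where c = 2f(1−f) + f² is the
Hardy-Weinberg carrier probability at control allele frequency f;
multiplier 1 is the null. Carriers are homozygous with the conditional HW
probability f²/c. Read depths are uniform on [20, 100] so the depth > 10
rule passes by default (`low_depth_fraction` plants shallow calls to
exercise it); true het allele fractions are uniform on [0.38, 0.62] and
true hom fractions on [0.95, 1.0], windows chosen so that integer rounding
of alt-read counts at depth ≥ 20 (error ≤ 0.025) cannot cross the QC
bounds. Artifact calls draw fractions from [0.08, 0.30] ∪ [0.70, 0.92]
(het) or [0.50, 0.85] (hom) and always fail QC, so the QC failure rate
estimates the artifact fraction exactly. Recurrent-artifact sites are
planted in a fixed number of samples (default 8 > the recurrence bound 5).
Recessive-spiked genes plant biallelic samples directly (two distinct het
sites, or one hom with probability 0.15).

The control summary is **deterministic** from the site frequencies
(AC = round(2Nf), AN = 2N, nhom = round(Nf²)) so that case-vs-control
discrepancies are attributable to case sampling alone; `sampled_controls`
switches to binomial draws.

The default study conditions — 50 cases, 200 genes × 10 sites at
f = 5·10⁻⁴, three spiked genes at multiplier 20 — are what the performance
suites run under: spike-in recovery (all three spiked genes at dominant
FDR < 0.05 and in the top five ranks in ≥ 90% of 50 seeds) and null
calibration (per-gene type-I at 0.05 below 0.05 + 3 binomial SE over 200
replicates).

What the generator does **not** model: linkage disequilibrium and
population structure (sites are independent, so `expected_biallelic` is
exact in-simulation but optimistic on real data), base-level sequencing
error (artifacts exist only at the allele-balance and recurrence level the
filters address), relatedness, annotation errors correlated across tools,
and case/control ancestry mismatch. Passing tests therefore demonstrate
the statistical machinery and filter logic, not robustness to those
real-data features.

## Numerical and interface choices

- Fisher exact tests are delegated to `scipy.stats.fisher_exact`; the test
  suite checks both alternatives against an exhaustive hypergeometric
  enumeration in exact integer arithmetic over randomized tables (10⁴
  tables with total ≤ 200) at 10⁻⁹ relative tolerance.
- BH is implemented directly (step-up with reverse cumulative minimum) to
  support the `m_total` extension; it is cross-checked against
  `statsmodels.multipletests(method="fdr_bh")` when the family is the
  input, and clamps q ≥ p against 1-ulp rounding in p·m/j.
- Parsed scores are capped at six significant digits, which removes float32
  INFO noise and makes VCF round trips exact; all simulated scores carry at
  most four decimals.
- Variant identity is the tuple (chrom, pos, ref, alt), 1-based, after
  pre-split normalization. Annotation keys are configurable through a field
  map supporting both plain INFO keys (the package's own writer's encoding,
  the default) and VEP-style CSQ subfields (`"CSQ:SYMBOL"`), since there is
  no single convention for how PredictSNP2-style tool counts are encoded.
- Degenerate inputs: empty cohorts, empty gene lists and empty collections
  yield empty results, not errors; an all-zero contingency table has p = 1;
  a zero-size term is k = 0, p = 1, direction "under"; a qualifying site
  missing from the control summary contributes zero control alleles
  (logged), since a variant unobserved in controls has no evidence of
  control carriers.
- Enrichment results sort by (p, term_id) and burden results by (p_dom,
  gene) so outputs are deterministic under ties.

## Problem sizes

The validation suites use 50 replicate cohorts for spike-in recovery, 200
for null calibration, 100 seeds for enrichment null behaviour, and 10⁴
random tables for the Fisher sweep; the complete test suite runs in under
a minute on one CPU, and `scripts/acceptance.py` in about half a minute.
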