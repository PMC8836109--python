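# Methods

## Scope and model

`famprio` prioritizes germline candidate variants in a single family under a
rare, highly penetrant, dominant-transmission hypothesis. The unit of
analysis is an already-annotated variant call: upstream read alignment,
variant calling and score annotation (CADD, GERP++, PhyloP, PhastCons,
gene-constraint metrics, dbNSFP-style predictor calls) are consumed, never
recomputed. Candidate selection is a conjunction of per-variant predicates
applied in a fixed order; because every stage is a pure per-variant filter,
the stage order affects only the intermediate survivor counts, never the
final candidate set (this is asserted by a permutation-invariance test).

### Segregation model

Phenotypes map to carrier expectations: cancer case → obligate carrier,
polyp patient → optional carrier (polyps as a possible precursor state),
unaffected-and-young → uninformative. A variant segregates iff all obligate
carriers carry it. Deliberately absent: any requirement that unaffected
members *not* carry the variant (incomplete penetrance makes that
constraint unsound, and observed candidate carrier sets differ in their
optional members), inheritance-mode likelihoods, founder checks, and de
novo modeling. Homozygous-alternate genotypes count as carrying by default
— the criterion is "carries the variant", not "is heterozygous" — with a
het-only mode available in `SegregationPolicy`. Per-member role overrides
are stored explicitly so manual reclassification stays auditable.

### Thresholds and boundary conventions

Defaults (all in `FilterConfig`, round-tripping through YAML):

| parameter | default | boundary |
|---|---|---|
| call quality | 20 | strict (>) |
| coverage | 5× | strict (>) |
| population MAF | 0.001 | inclusive (≤) |
| local cohort frequency | 0.05 | strict (<) |
| CADD (PHRED) | 10 | inclusive (≥) |
| GERP++ | 2.0 | inclusive (≥) |
| PhastCons | 0.3 | strict (>) |
| PhyloP | 3.0 | inclusive (≥) |
| conservation criteria required | 2 of 3 | ≥ count |
| intolerance fraction | 0.60 | inclusive (≥) |
| deleteriousness fraction | 0.60 | inclusive (≥) |
| VEST3 | 0.5 | inclusive (≥) |
| reliability index | 5 | inclusive (≥) |

The mixture of strict and inclusive bounds is intentional, mirroring the
operator each criterion is conventionally stated with rather than
normalizing them. The 60% fractions must be inclusive: a candidate sitting
exactly at 3-of-5 intolerance is a documented survivor.

### Missing data

Three explicit policies, all fail-closed where ambiguity would otherwise
inflate the candidate list:

- **Frequencies** (`treat_as_rare`, default): a variant absent from the
  population panels passes the frequency stage — absence from large
  reference cohorts is itself evidence of rarity. The alternative (`drop`)
  fails any variant with a missing frequency.
- **Conservation**: a missing score counts as unsatisfied; the denominator
  stays 3, because the rule is a fixed "2 of 3", not a proportion.
- **Panel fractions** (`exclude_from_denominator`, default): percentages
  are computed over non-missing panel members, so a variant annotated by
  only 6 of 12 predictors is judged on those 6. A fully missing panel
  fails. The alternative (`count_unfavorable`) fixes the denominator at the
  full panel size. The intolerance panel pools all five available members
  (three ratio scores, Z, pLI) regardless of variant type; restricting Z to
  missense and pLI to loss-of-function variants is expressible through the
  missing-score mechanism but is not the default, since the five-member
  pool is what the observed panel percentages imply.

### Exact carrier test

The cohort screen compares carrier counts between case and control groups
with the standard two-sided exact convention: condition on the table
margins and sum the hypergeometric probabilities of every table whose point
probability does not exceed the observed one. Tables are selected by exact
integer weight (`comb(n1, x) * comb(n2, k − x)`), so probability ties —
which occur systematically in symmetric tables — are never lost to
floating-point comparison; only the final summation is in floats. The odds
ratio is the sample cross-product estimate and is flagged `unbounded`
(rather than reported as 0 or ∞) whenever a cell is zero, the typical
situation when no control carriers are found. Tests validate the p-value
against an independent rational-arithmetic enumeration to 1e-12 and against
`scipy.stats.fisher_exact`.

### Alignment audit

`column_identity` quantifies cross-species conservation of the residue a
missense variant alters: the fraction of non-reference rows matching the
reference residue at a 1-based alignment column, gaps counting as mismatch.
Input must be pre-aligned FASTA; no aligner is embedded. The bundled
six-species alignment is a constructed synthetic stand-in (the real
alignment of the motivating gene is not redistributable); it preserves the
salient feature — full identity at the audited column, variation elsewhere
— so the audit is exercised honestly, but it carries no biological
information about the real protein.

## Synthetic data generator

The generator emulates the post-frequency-filter variant pool of a family
exome study so the funnel can be exercised end to end without patient data.

- **Genotypes** are gene-dropped: founder alleles (and alleles from parents
  not listed in the pedigree, e.g. unsequenced spouses) are Bernoulli draws
  at a per-variant founder allele frequency ~ Uniform(0.05, 0.5); children
  inherit one allele from each parent uniformly. Background variants are
  generated under the null of no linkage to disease, so their survival of
  the segregation stage estimates that filter's false-pass rate under
  within-family allele sharing alone. Rows are resampled until at least one
  sequenced member carries an alternate allele, reflecting that a real pool
  contains only variants actually called in the family; the moderate founder
  frequencies likewise stand in for this ascertainment, not for population
  MAFs.
- **Annotations** come from a two-regime mixture (5% deleterious-like by
  default). The benign regime centers every score below its threshold
  (CADD ~ N(3, 3²) clipped at 0, GERP ~ N(0, 1.5²), PhyloP ~ N(0, 1),
  PhastCons ~ Beta(1, 4), panel favorable probabilities 0.25/0.10); the
  deleterious regime centers above (CADD ~ N(25, 6²), GERP ~ N(4.5, 1),
  PhyloP ~ N(5, 1.5²), PhastCons ~ Beta(8, 1), favorable probabilities
  0.85). Region classes are drawn so roughly one variant in six is coding,
  and ~55% of coding variants are non-synonymous; 2% of rows get common
  population frequencies and 1% high local frequencies so the frequency
  stage has work to do. Per-predictor missingness is 10% (benign) / 5%
  (deleterious).
- **Planted variants** are appended with exactly their specified
  annotations and carrier sets (everyone else homozygous reference), and
  their identifiers are returned as `SyntheticTruth` for recovery tests.

What the generator does **not** emulate: linkage disequilibrium and shared
haplotypes (each variant is dropped independently), calling noise
correlated with depth, gene-level score catalogs, and realistic
chromosome/position structure. Consequently the synthetic per-stage counts
— in particular the segregation survival fraction — characterize the filter
logic, not any real dataset, and the tests treat them only as monotonicity
and recovery properties, never as quantities to match a study.

## Problem sizes and numerics

The default synthetic scale is 10⁴ background variants, matching the size
of a realistic post-frequency-filter family pool; the planted-recovery
property is checked over 100 seeds at 5,000 background variants each, which
the vectorized generator completes in well under a minute per batch of
seeds. Exhaustive oracles are used wherever the space is small enough to
enumerate: all 2¹² deleteriousness panels, all 3⁵ intolerance panels, all
4⁶ genotype assignments of the six-member family, and all small 2×2 tables
for the exact test. All randomness flows through `numpy.random.default_rng`
seeded from `SimulationParams.seed`; a fixed seed yields byte-identical
output files. Final candidates are ranked by CADD descending with
chromosome/position tie-breaks — a presentation convention only, since the
surviving set is ranking-independent.

## Known limitations

- Single-family analysis only; no multi-family joint modeling.
- The funnel is a hard conjunction: one failed stage removes a variant with
  no recovery, and no weighting or score combination across stages is
  attempted.
- The carrier screen is unadjusted for population stratification and makes
  no penetrance statement.
- Annotation-table parsing targets the documented column convention, not
  the full matrix of annotation-tool output dialects.
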