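# famprio — family-based germline variant prioritization

`famprio` implements a tiered filtering funnel for finding candidate
predisposition variants in a cancer family from whole-exome variant calls.
It is written for statistical-genetics and cancer-genomics analysts who have
an annotated rare-variant table (ANNOVAR-style TSV: one row per variant with
population frequencies, per-position conservation scores, gene-level
constraint metrics, a panel of deleteriousness predictor calls, and one
genotype column per sequenced relative) plus a pedigree, and who want a
reproducible, auditable path from ~10⁴ rare variants down to a handful of
candidates.

## The model

Variants pass through a fixed sequence of per-variant filters; survivors of
each stage are exactly the inputs of the next:

1. **QC** — call quality > 20 and coverage > 5× (strict bounds).
2. **Frequency** — every available population MAF ≤ 0.1% (1000 Genomes,
   non-TCGA ExAC, gnomAD NFE) and local cohort frequency < 5%; a missing
   frequency is treated as rare by default (configurable).
3. **Pedigree segregation** — under a dominant carrier-expectation model,
   affected cases are *obligate carriers*, polyp patients *optional
   carriers*, and relatives below the family's earliest onset age
   *uninformative*. A variant segregates iff every obligate carrier
   carries it (het or hom-alt); nobody is required to be a non-carrier.
4. **Coding** — keep exonic and splicing variants.
5. **Non-synonymous** — drop synonymous calls; keep amino-acid-changing,
   frameshift, stop-altering and unclassifiable exonic calls.
6. **CADD** — PHRED-scaled CADD ≥ 10 (≈ top decile of deleteriousness).
7. **Conservation** — at least 2 of 3 among GERP++ ≥ 2.0, PhastCons > 0.3,
   PhyloP ≥ 3.0 (missing scores count as unsatisfied; denominator fixed at 3).
8. **Intolerance** — ≥ 60% favorable among the available members of a
   five-score gene panel: three ratio-based intolerance scores (< 0),
   missense constraint Z (> 0), pLI (≥ 0.9).
9. **Deleteriousness** — ≥ 60% favorable among the non-missing members of a
   12-call predictor panel (SIFT, PolyPhen-2 HumDiv/HumVar, LRT,
   MutationTaster, MutationAssessor, FATHMM, MetaSVM, MetaLR, VEST3,
   PROVEAN, and a prediction reliability index).

Every threshold, boundary convention and missing-data policy lives in a
YAML-serializable `FilterConfig`; every stage decision carries an audit
detail map (numerator and denominator for the panel fractions).

The package also provides a validation-cohort **carrier screen** (carrier
tally per group plus a two-sided exact test on the 2×2 table, computed by
hypergeometric enumeration with exact tie handling), an **alignment audit**
(cross-species identity of the residue a missense variant disturbs), and a
seeded **synthetic data generator** that gene-drops genotypes Mendelianly
through a pedigree and draws annotations from benign-like and
deleterious-like regimes, so the whole funnel is testable end to end
without any protected patient data.

## Worked example

The package bundles a six-member colorectal-cancer family (three cases, two
polyp patients, one young unaffected member) and the six exonic candidate
variants that emerge from its exome screen:

```python
from famprio import run_funnel, candidate_report
from famprio.datasets import crc_candidate_variants, crc_family_pedigree

table = crc_candidate_variants()
pedigree = crc_family_pedigree()
report, final = run_funnel(table, pedigree)
for stage, count in report.stages:
    print(f"{stage:16s} {count}")
```

```
input            6
qc               6
frequency        6
segregation      6
cadd             6
...
deleteriousness  6
```

All six candidates survive every stage — they are the funnel's fixed point —
and `candidate_report(final)` ranks them by CADD (ties by position):

```
gene       variant                cadd_phred deleteriousness_pct intolerance_pct
RSBN1L     7_77407669_G_A               35.0   100.00    80.00
ADAMTS10   19_8670022_C_T               32.0    66.67    80.00
PTK7       6_43100257_G_A               25.3    66.67   100.00
C2orf42    2_70387896_G_C               23.5    83.33    60.00
GNA13      17_63049685_T_C              22.3    75.00    60.00
TNIP1      5_150431736_C_T             19.16    66.67    60.00
```

The percentages are recomputed from the bundled predictor panels — e.g.
C2orf42's 83.33% is 5 favorable of 6 annotated predictors, and GNA13 sits
exactly on the inclusive 60% intolerance boundary (3 of 5). Choosing among
the finalists (somatic alteration frequency, driver predictions, literature)
is a judgment step outside the algorithmic scope; such annotations ride
along as passthrough columns.

The same pipeline runs from the shell:

```sh
prioritize show-config                       # print default thresholds
prioritize simulate --seed 3 --out sim/      # synthetic table + PED + truth
prioritize run --variants sim/variants.tsv --ped sim/family.ped --out out/
prioritize screen --calls calls.tsv          # cohort carrier tally + exact test
```

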