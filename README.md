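# varprio

Customizable weighted-sum prioritization of annotated genetic variants, with
hard filters, per-sample genotype quality control, and pedigree-aware
post-processing (candidate-gene, case-control and Mendelian trio
inheritance-model filters).

## The problem

A sequenced rare-disease family yields 10⁵–10⁷ variants. Annotation tools
(ANNOVAR, VEP) decorate each variant with consequence classes, population
frequencies and many in-silico pathogenicity predictors — but no single
predictor is reliable on its own, and combining them by hand is laborious.
`varprio` collapses any number of annotation columns into one configurable
priority score so the whole call set can be ranked at once, then lets the
analyst cut the ranked list down by family structure.

## The method

Everything is driven by a plain-text **prioritization parameter file (PPF)**:

* **Filters** drop variants outright, e.g. population minor allele frequency
  above 0.1% (`gnomAD_AF > 0.001`; a variant *absent* from the frequency
  database passes — absence is evidence of rarity) or synonymous calls.
* **Scoring rules** assign integer weights to annotation values, either
  categorical literals (`ExonicFunc.refGene == stopgain → +5`) or half-open
  numeric intervals (`CADD_phred ∈ [20, ∞) → +2`). A variant's raw priority
  score is

  `S = Σ_fields max{ w_r : rule r on that field matches }`,

  and its normalized score is `S / S_max` over all surviving variants.
  Variants with `S` below a configurable cutoff are excluded; survivors are
  ranked by descending normalized score (ties broken by chromosome,
  position, ref, alt).
* **Genotype QC** encodes each sample at each variant as `0` (reference),
  `1` (heterozygous), `2` (homozygous alternate) or `.` when the call fails
  QC: coverage below 8 reads or allele balance outside `[0.25, 0.75]` by
  default.

The ranked table — the **variant priority ordered list (VPOL)** — can then be
post-processed: `stats` (per-sample report of genes in the top 75th
percentile of scores), `genef` (candidate gene list), `samplef` with
case-control (`cc`) or trio inheritance models (de novo `DN`, autosomal
dominant `AD`, autosomal recessive `AR`, compound heterozygous `CH`), and
`merge` to consolidate per-sample chunk runs back into one cohort-wide list
— bit-identical to a single whole-cohort run.

A default PPF for rare-disease screening ships with the package
(`varprio.default_ppf_path()`); every weight and threshold in it is editable.

## Worked example

A seeded synthetic consanguineous trio with 2000 background variants and a
planted rare homozygous stop-gain in *HAAO* (proband `1/1`, both parents
`0/1`):

```sh
$ varprio fixtures --out-dir demo --seed 11 --n-background 2000 --plant-model AR
$ varprio priority -I demo/cohort.vcf -P "$(python -c 'import varprio; print(varprio.default_ppf_path())')" \
      -O demo/cohort.vpol
INFO varprio.prioritize: prioritize: 2001 variants in, 1458 removed by filters, 0 below cutoff, 543 ranked
$ varprio samplef -I demo/cohort.vpol -F demo/cohort.ped --model AR -O demo/ar.vpol
INFO varprio: samplef AR: 1 of 543 records kept
$ varprio stats -I demo/ar.vpol
scored variants 1
normalized-score threshold (top 75th percentile)  1
sample  F0.P   carried variants  1  top-percentile genes  HAAO
sample  F0.FA  carried variants  1  top-percentile genes  HAAO
sample  F0.MO  carried variants  1  top-percentile genes  HAAO
```

Of 2001 variants, 1458 are removed by the frequency/synonymous filters; the
recessive trio filter then reduces the 543 ranked survivors to exactly the
planted variant, which holds rank 1 with raw score 15 (stop-gain 5, CADD 39
≥ 20 → 2, damaging PolyPhen-2/MutationTaster2/MetaSVM 2+2+2, LRT 1,
GERP++ 5.26 ≥ 4 → 1) and normalized score 1.0:

```
Rank  Priority_Score  Normalized_Score  Chr  Pos       Ref  Alt  Gene.refGene ...  F0.P  F0.FA  F0.MO
1     15              1.0               2    43013958  G    A    HAAO         ...  2     1      1
```

The same workflow is available as library calls (`read_annotated_vcf`,
`prioritize`, `filter_inheritance`, …); see the module docstrings.

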