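# Methods

## Model

`varprio` ranks annotated variants by a weighted sum over annotation fields.
For a variant with annotation map `a` and a parameter file with scoring
rules `R`, the raw priority score is

    S(a) = Σ_f  max { w_r : r ∈ R_f, r matches a[f] }        (0 if no match)

where `R_f` are the rules on field `f`. Categorical rules match an exact
raw-string literal; numeric rules match the half-open interval
`[lower, upper)` after parsing the value as a float. One convention is used
for every interval (lower-inclusive, upper-exclusive, infinite bounds
allowed) so a "≥ 20" rule is written `[20, ∞)` and boundary behaviour never
drifts between rules. When several rules on the same field match (e.g.
overlapping intervals), the **maximum** weight applies — deterministic and
order-independent; the validator warns about overlaps. Missing values (the
canonical token `.`, to which empty cells and `NA` are normalized at read
time) match nothing and contribute 0. Weights are integers and may be
negative.

Normalization divides by the maximum raw score among variants that survive
filtering and the raw-score cutoff: `S_norm = S / S_max`. The cutoff is
compared against the **raw** score (`S ≥ cutoff` keeps the variant), because
a raw threshold is reproducible across cohorts while normalized values are
cohort-relative. When `S_max ≤ 0` all normalized scores are set to 0, and a
negative raw score under a positive `S_max` is clamped to 0, keeping
`0 ≤ S_norm ≤ 1` always. Ranking order is total and deterministic:
descending normalized score, then chromosome (string compare, labels kept
verbatim), position, ref, alt.

Scoring is a pure per-variant function given `S_max`, so per-sample chunked
runs merged afterwards are bit-identical to a single whole-cohort run; this
is verified, not assumed.

## Hard filters

Filter rules drop variants before scoring: `equals` (literal match),
`greater`/`less` (numeric threshold). Each rule carries a `missing_passes`
flag, default **true**: for population-frequency fields, absence from the
database is evidence of rarity, so an unobserved variant must not be
discarded by a frequency screen. Unparseable numeric values are treated as
missing and logged rather than aborting a whole-genome run. The decision is
order-independent (any triggering rule drops the variant).

## Genotype quality control and encoding

Each sample's call at each variant is encoded `0`/`1`/`2`/`.`. QC uses
coverage (`DP`, or the `AD` sum when `DP` is absent) and allele balance
(`AD[alt] / depth`):

* missing call → `.`
* non-reference call with depth < `min_depth` (default 8) → `.`
* heterozygote with allele balance outside
  `[min_allele_balance, 1 − min_allele_balance]` (default 0.25) → `.`
* homozygous-alternate with balance < `1 − min_allele_balance` → `.`

Two deliberate asymmetries: reference-homozygous calls are never
depth-masked (masking them would erase the control information that
case-control filtering relies on), and a check whose inputs are absent from
the source file (no `DP`/`AD`) passes — it cannot be disproven — with the
situation logged. The homozygote bound uses the same symmetric band as the
heterozygote test rather than a separate parameter.

## Post-processing

All post-filters return a subset of the input with scores untouched and
ranks reassigned, hence they are idempotent. `.` genotypes are
non-informative everywhere: they never count as carrying, so a QC-failed
control cannot rescue a variant and a QC-failed parent defeats a de novo
claim (fail-closed).

* **stats** — the percentile threshold uses the nearest-rank definition on
  normalized scores (the `ceil(p/100·n)`-th smallest); no interpolation, so
  the threshold is always an observed score and the result is deterministic.
  Genes are reported per sample when the sample carries (`1`/`2`) a variant
  at or above the threshold.
* **genef** — multi-gene annotation cells are split on `;` and `,`; matching
  is exact and case-sensitive.
* **case-control** — keep variants carried by ≥ 1 affected and by no
  unaffected sample; unknown-status samples are ignored.
* **inheritance models** (complete trio required, resolved from the PED file
  as the unique affected proband whose parents are both present): de novo —
  proband `1`/`2`, both parents `0`; dominant — proband `1`, affected parent
  `1`, unaffected parent `0` (exactly one affected parent required; a `2`
  proband or parent is deliberately not accepted — the classic dominant
  heterozygote is required); recessive — proband `2`, both parents `1`;
  compound heterozygous — heterozygous proband variants in genes containing
  both a paternal-specific (father carries, mother `0`) and a
  maternal-specific variant. X-linked and mitochondrial inheritance are out
  of scope.
* **merge** — refuses inputs with different annotation field sets or
  conflicting raw scores at one site (scores from different parameter files
  are not comparable), requires disjoint sample sets, fills sites absent
  from an input with `0` for that input's samples, and renormalizes against
  the merged maximum.

## Input handling

VCF parsing is delegated to pysam/htslib (plain, BGZF, and — via a
decompression fallback — vanilla gzip). Multi-allelic records are split into
one record per alternate allele at read time: scoring and genotype encoding
are per-allele concepts. Per-allele comma lists (`AD`, `Number=A` INFO) are
apportioned to the matching allele; line-level annotations are copied to
every split allele. Coordinates stay in VCF convention (1-based, chromosome
labels verbatim — no `chr` normalization). When no explicit field list is
given, every INFO key declared in the header populates every record (absent
keys become `.`), so all records share one field set. Phased separators are
treated like unphased; variants without a gene symbol are kept (symbol
`.`). TSV input accepts any annotation software's output (header row,
`Chr/Pos/Ref/Alt` coordinate columns by default, VCF-style or pre-encoded
genotype cells in designated sample columns).

## The default parameter file

The shipped `data/default.ppf` encodes a rare-disease screen: exclude
population MAF > 0.1% (gnomAD/ExAC/1000 Genomes fields) and synonymous
calls; QC at 8 reads / 0.25 balance; weights 5 for stop-gain, frameshift
insertion/deletion and splicing (4 for stop-loss), 1 for missense, and
predictor contributions at the thresholds their authors publish — CADD phred
≥ 20 → 2 (10–20 → 1), GERP++ RS ≥ 4 → 1, damaging PolyPhen-2 (`D` 2 / `P`
1), MutationTaster2 (`A`/`D` 2), LRT (`D` 1), MetaSVM (`D` 2). The specific
integer weights are this package's own calibration choice — weighting is
precisely the user-tunable part of the method — and the file is meant to be
edited. The GERP++ field is spelled `GERPpp_RS` because `+` is not valid in
a VCF INFO ID.

## Synthetic cohorts

The fixture generator emulates a family sequencing study so every pipeline
stage is testable without external data. Families are trios, quartets or
consanguineous trios. Background variants draw their population frequency
from a mixture — half common, uniform on [0.01, 0.5] (these exercise the
frequency filter), half rare, log-uniform on [10⁻⁶, 10⁻³] — and their
annotations from simple parametric distributions (90% exonic — of which 50%
synonymous, 45% missense, 5% in-frame deletion — and 10% intronic; CADD
normal around 15 for missense, 5 otherwise; predictor categories skewed
benign). Parental genotypes are Hardy–Weinberg draws at the variant's
frequency; children inherit one allele from each parent, so all background
genotypes are Mendelian-consistent. Read depths are Poisson (mean 35) with a
2% shallow-coverage fraction and 1% missing calls, so genotype-QC failures
occur at a realistic rate. A planted causal variant (configurable gene,
consequence and inheritance model) gets clean depths and a
damaging-across-the-board annotation profile; under the default PPF it
scores 15 while the background missense ceiling is 11, so recovery failures
can only come from QC masking a planted genotype (binomial allele-balance
draws), not from scoring. The generator does **not** emulate linkage,
haplotype structure, sequencing error profiles or annotation disagreement
patterns of real predictors — passing recovery tests demonstrates the
pipeline's mechanics, not performance on real genomes. Identical
configuration and seed regenerate byte-identical files.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down cohorts chosen to exercise
every code path with comfortable margins: 200 random rule-set fixtures
(≤ 100 variants × ≤ 20 fields) for the scoring oracle, the full 4³ genotype
enumeration plus 1000 random gene configurations for inheritance models, 100
seeded 5000-variant consanguineous-trio cohorts for planted-variant
recovery, and 20 cohorts for chunk/merge equivalence. All randomness flows
from explicit seeds. Score arithmetic is integer; the only floating-point
quantities are normalized scores (written with full `repr` precision so file
round-trips are exact) and interval bounds.

## Known limitations

Structural variants, BCF, and phased-genotype semantics beyond treating `|`
as `/` are unsupported. The dominant model assumes a single affected parent;
multi-family VPOLs must be split per family before inheritance filtering
(trio resolution requires uniqueness). Gene-symbol matching is string-exact;
no alias resolution. The compound-heterozygous filter works on encoded
genotypes, not phase — it cannot distinguish true trans configurations from
two variants inherited on one haplotype when both parents carry variants in
the same gene.
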