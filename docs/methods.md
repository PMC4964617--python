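# Methods

## Model and pipeline

`epiprior` operationalizes a promoter-centric integrative analysis: given a
set of disease-associated genes and a collection of epigenomic element
tracks (TFBS ChIP-seq peaks, chromatin-state segments, histone-mark peaks,
each specific to one cell type), it asks which elements mark the disease
promoters more or less often than chance, and then ranks all genes by how
strongly their promoters carry that disease profile.

**Promoters.** The promoter of a transcript is the `L = 2000` nt window
immediately upstream of its TSS: `[tss − L, tss)` on the + strand,
`[tss, tss + L)` on the − strand, clipped to the chromosome. The TSS base
itself is excluded; the common upstream-window definition is ambiguous on
this point and the half-open exclusion keeps windows exactly L long and
composable in BED coordinates. A gene's promoter is the per-gene union of
its transcript windows (merged only within a gene — promoters of different
genes may overlap each other and are counted separately, because the
analysis is per gene).

**Annotation.** A promoter is annotated by an element if any of its
fragments shares ≥ 1 base with any track interval. Two quantities are kept
per (gene, element): the binary flag (repeated overlap counts once — this
feeds the enrichment test) and the number of distinct track intervals
overlapping the promoter union (feeds the scoring stage). A single interval
spanning two fragments of one gene is one annotation event. Element strand
is ignored (peak tracks are unstranded); the same mark assayed in two cell
types is two distinct elements. Overlap is computed with an interval tree
over promoter fragments; the tests verify equivalence with a brute-force
all-pairs scan.

**Enrichment.** The null model is resampling: 1,000 draws (default) of
`|D|` genes uniformly without replacement from *all* genes, where `D` is
the disease set; per element the annotated count in each draw is recorded,
giving the background mean and variance. The observed disease count is then
tested against the rounded background mean with a two-sided Fisher exact
test on the table

```
[ observed,            |D| − observed           ]
[ round(bg mean),      |D| − round(bg mean)     ]
```

The coupling of a resampled background with Fisher's test admits more than
one 2×2 construction; this one keeps both columns on the disease-set scale
and is the primary p value. Two companions are always reported: a pooled
variant testing observed/|D| against the all-genes annotated fraction, and
an add-one empirical permutation p,
`(1 + #{resamples at least as extreme in the observed direction}) / (n + 1)`,
which cannot be zero. Direction is `enriched` when observed ≥ background
mean, else `depleted`; for reporting, p values are signed:
`−log10 p` for enriched (positive), `+log10 p` for depleted (negative).
Element significance defaults to raw Fisher `p < α = 0.05` (configurable;
BH-adjusted p values are computed for all elements and can be used
instead). A control run repeats the whole procedure on a random gene set of
the same size; on null data its significant fraction sits at or below α —
the Fisher-vs-expected-mean construction is conservative because the
background column carries almost no sampling variance, so the realized
type-I rate is below nominal (the calibration test brackets it within
3 binomial SD of α).

**Prioritization (reverse prediction).** With significant elements `S` and
weights `w_e = signed log10 p_e`, a gene's total score is
`Σ_{e∈S} counts[g, e] · w_e`. Default `signed` mode lets depleted elements
subtract — a gene matching the disease profile both carries the enriched
marks and avoids the depleted ones; `absolute` mode (`|w_e|`) is provided
because published total-score tables are uniformly positive and the
summation convention there is not fully specified. Ranking is descending by
score with deterministic lexicographic tie-break on gene id; known disease
genes are excluded from the candidate table by default (they are scored and
written separately), and the top k = 20 is reported with scores at 2
decimals.

**Association statistics.** Candidate validation uses allele-count
statistics reconstructable from printed summary data. From minor-allele
frequencies and sample sizes, allele counts are `a = round(2·n_cases·MAF)`
etc. (integer rounding default; fractional mode keeps exact products). The
allelic OR is `(a/b)/(c/d)` with Woolf CI
`exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))` and a two-sided normal test on
`ln OR / SE`; any zero cell triggers the Haldane–Anscombe +0.5 correction.
Meta-analysis combines signed per-study Z scores with square-root-of-n
weights, `Z = Σ zᵢ√nᵢ / √Σnᵢ`, invariant under uniform rescaling of the
nᵢ. Heterogeneity uses fixed-effect inverse-variance weights:
`Q = Σ wᵢ(βᵢ − β̄)²`, p from χ²(k−1), `I² = max(0, (Q − df)/Q)·100`.
Multiple testing uses Benjamini–Hochberg step-up (via statsmodels; a hand
step-up oracle guards it in the tests). Note the reconstruction from
rounded printed MAFs recovers published ORs only to the printed precision;
published values from covariate-adjusted regression can differ in the last
digit (observed for two of the six reconstruction targets, 0.59 vs 0.58
and 1.05 vs 1.04).

## Synthetic data generator

The generator emulates the shape of the real inputs — a gene model with
per-transcript TSSs, element interval tracks, a disease gene list — at a
desk scale chosen to mirror a realistic study: 2,000 genes (default) with a
250-gene disease set (real GWAS-derived disease gene lists run to a few
hundred genes), 2,000-nt promoters, tracks with a baseline promoter-hit
probability around 0.2.

Genes are laid out in disjoint chromosome slots wide enough (≥ 5L + 1 per
gene) that promoters of neighbouring genes can never touch; transcript
TSSs sit within one promoter length of the gene anchor so multi-transcript
promoters genuinely overlap and exercise merging. For each element, every
gene's promoter is hit independently with probability `p_b`
(`baseline_hit_prob`) for background genes and

```
p_planted = m·odds_b / (1 + m·odds_b),   odds_b = p_b / (1 − p_b)
```

for planted genes, where `m` is the `planted_odds_multiplier` (m = 1 null,
m > 1 enrichment, m < 1 depletion). Odds — not probability — is multiplied
so any m keeps the probability in (0, 1). A hit places `intervals_per_hit`
intervals (default 1, length 200 bp, a typical ChIP peak width) at uniform
positions overlapping the promoter by ≥ 1 base; `n_intergenic_intervals`
(default 25) noise intervals per track land uniformly in promoter-free
space. A single integer seed drives everything through per-operation child
streams, so each operation is independently reproducible and the whole
dataset is a pure function of its config.

What the generator does *not* emulate: sequence content, GC/length-matched
element placement, linkage disequilibrium, correlated elements (each track
hits genes independently), overlapping promoters of neighbouring genes, and
chromosome-scale heterogeneity of element density. Passing calibration and
recovery tests on this model therefore show the statistics behave correctly
under an idealized independence null, not that real ENCODE tracks meet that
null; with real data the resampling background absorbs overall density but
not positional confounding.

**A ceiling worth knowing.** With k independent elements whose hit
probabilities are `p_planted` vs `p_b`, the per-gene hit count is a
sufficient statistic, so no scoring rule can separate planted from
background genes better than the binomial count ranking. Its tie-credit
AUC for k = 5, `p_b = 0.2`, m = 3 (`p_planted = 3/7`) is exactly 0.7786 —
observed medians across seeds land there (≈ 0.78–0.80). Stronger separation
requires more planted elements, larger multipliers, or correlated planting,
not a better scorer.

## Numerical choices

- Fisher's two-sided p sums hypergeometric point probabilities
  ≤ (1 + 1e−7) × the observed table's probability; the relative tolerance
  absorbs floating-point ties among equally-probable tables. A zero margin
  returns p = 1 with a logged warning.
- `signed_log10` rejects p ≤ 0; the empirical p's add-one smoothing keeps
  it strictly positive, and Fisher p values are bounded below by the
  table's point probability.
- Ties in ranking break lexicographically on gene id — deterministic and
  reproducible across platforms.
- `observed == background mean` yields Fisher p = 1, signed log p = 0, and
  direction `enriched` by the non-strict inequality (the value is ±0
  either way).
- Resampling draws from all genes, disease genes included — the background
  is the whole genome, and excluding the disease set would bias the null
  low for enriched elements.
- All result TSVs are written with `%.6g` floats so reruns are
  byte-identical.

## Limitations

- The enrichment p is conservative by construction (see above); empirical
  and pooled p values are reported for sensitivity.
- No genomic-position-preserving null (matched GC, length, or distance to
  TSS); elements whose placement correlates with promoter density will
  appear enriched for structural rather than disease-specific reasons on
  real data.
- Association statistics are allelic and unadjusted; they reconstruct
  printed summary tables but are no substitute for covariate-adjusted
  genotype-level regression.
- The pipeline scales to hundreds of tracks × tens of thousands of genes
  in memory (dense gene × element matrices); it is not engineered for
  single-base signal tracks or bigWig input.
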