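# Methods

## Scope and model

`phenoprio` ranks candidate disease genes in a single-sample exome by
combining two independent lines of evidence:

1. **Genotype evidence** — how rare and how damaging the patient's
   surviving variants are under each mode of inheritance (MOI);
2. **Phenotype evidence** — how similar the patient's HPO-encoded
   presentation is to the known phenotypes of each gene, across human
   disease annotations, mouse and zebrafish models, and
   protein-interaction neighbours.

The analysis is singleton-only: no pedigree, no phasing, no structural
variants, and no transcript re-annotation (the consequence class is read
from the VCF `CSQ`/`GENE` INFO keys or must be supplied upstream).

## Filter cascade

Steps run in the configured order; each is a pure per-variant predicate,
so the surviving set is order-independent.

* `analysisMode: PASS_ONLY` drops records whose FILTER is neither `PASS`
  nor `.` at parse time.  `.` is treated as PASS: a missing FILTER value
  makes no claim, and dropping such records would silently discard
  unrecalibrated call sets.
* `qualityFilter` — call quality ≥ `minQuality` (default 30), boundary
  inclusive; a missing QUAL fails.
* `variantEffectFilter` — removes non-coding consequence classes (UTR,
  intronic, intergenic, up/downstream, regulatory, non-coding transcript).
  Whitelisted variants bypass.
* `frequencyFilter` — maximum MAF across the selected reference sources
  ≤ `maxFrequency` (default 2, percent scale, inclusive).  Whitelist
  bypasses.  All cutoffs are percent; the per-MOI defaults (AD/XD 0.1,
  AR/XR homozygous 0.5, compound-heterozygous 2.0) are applied again at
  genotype assembly.
* `inheritanceFilter` — genotype assembly per MOI sub-mode: dominant
  singletons, recessive homozygotes, all unordered pairs of heterozygous
  calls for compound heterozygotes (no cis/trans check — singletons carry
  no phase information), hemizygotes on X, and mitochondrial singletons
  (heteroplasmy ignored; the genotype call is taken at face value).
  A heterozygous call can never satisfy a homozygous/hemizygous mode; this
  is what removes causal variants that an upstream caller mis-genotyped.
  With unknown sample sex an X-chromosome homozygote is considered under
  both the autosomal- and X-recessive homozygous modes; with a male-coded
  sample it is treated as hemizygous.  X-dominant is handled symmetrically
  to autosomal dominant on X.
* `pathogenicityFilter` with `keepNonPathogenic: true` (the default) is a
  no-op; when disabled it drops variants whose pathogenicity score is
  below 0.5 after scoring (whitelist exempt).

## Variant and genotype scores

The frequency score is `1.13533 − 0.13533·e^f` with `f` the maximum MAF.
The exponential is written against the allele frequency as a *proportion*
scaled by 100, which is numerically identical to using the percent value
directly; the implementation therefore works entirely on the percent
scale, pins the score to 1 at `f = 0`, and clips to 0 for `f > 2` percent
(the raw formula would cross zero near 2.127).

Pathogenicity-source normalization: SIFT → `1 − raw`; CADD phred →
`1 − 10^(−raw/10)`; PolyPhen-2, MutationTaster, REVEL, M-CAP, MPC, MVP and
PrimateAI are consumed as pathogenicity probabilities and clamped.  The
variant's pathogenicity score is the maximum over the *selected* sources.
Overrides, in order of precedence:

| rule | score |
|---|---|
| frameshift, nonsense, canonical splice acceptor/donor, stop-loss, start-loss | 1.0 fixed |
| splice region | 0.8 fixed |
| no selected source has data | consequence preset |

Preset table: in-frame insertion/deletion 0.85, missense 0.6, synonymous
0.1, other (non-coding) classes 0.0.  Only the in-frame value is anchored
by a documented case; the others are package defaults chosen monotone with
clinical severity.  A whitelisted variant scores 1.0 regardless of both
factors.  A compound-heterozygote genotype scores the arithmetic mean of
its two variant scores; every other genotype scores its single variant.
Within each gene and MOI the best-scoring genotype is selected and its
variants flagged *contributing*; ties break deterministically by higher
pathogenicity, then lower frequency, then genomic position.  Reported
scores are rounded to 3 decimals (round-half-even); internal arithmetic is
full precision.

## Phenotype score

Term-level similarity is `sqrt(J(q,h) · IC(MICA(q,h)))` with reflexive
ancestor sets.  Information content uses the natural log (the scale
cancels in the normalized profile score) over a corpus with one entity per
annotated model; terms with no annotated descendants get an add-one floor
(`n ← max(n, 1)`) so IC stays finite on sparse corpora.  MICA ties break
on the lexicographically smallest term id.  Multi-rooted ontologies are
allowed; cross-root pairs score 0.

Profile similarity against a model profile: for each query term take the
best term-level score against the model; then

    score = 0.5 · (best/ideal_best + mean/ideal_mean)

where the ideals are the same quantities for the query against itself.
This makes self-similarity exactly 1 and keeps the score in [0, 1].  It is
deliberately asymmetric (query-anchored): un-matched *model* terms do not
dilute the score, which is the desired behavior when database annotations
are richer than a parsimonious clinical profile.

A gene's phenotype score is the maximum over its own models and over
neighbour evidence, where a neighbour model's similarity is scaled by
`neighbor_weight × edge confidence`.  `neighbor_weight` defaults to 0.75:
it must be strictly below 1 so that direct annotation dominates
equal-quality neighbour evidence, and 0.75 keeps a confident neighbour
(confidence ≈ 0.9) in the 0.5–0.7 band observed for neighbour-derived
matches.

**MOI-consistency penalty** (the `omimPrioritiser` step): if the winning
match is the gene's *own* human-disease annotation with a known MOI that
is inconsistent with the candidate genotype's MOI, the phenotype score is
halved, once.  Consistency is group-wise: dominant annotations (AD/XD)
match dominant candidates, recessive (AR/XR) match recessive candidates,
mitochondrial matches mitochondrial, UNKNOWN never penalizes.  Only the
single best-matching disease is consulted — a second disease entry with a
different MOI does not rescue the score — and matches won by organism
models or via a neighbour are exempt.

## Combined score and ranking

`logistic(β₀ + β₁·genotype + β₂·phenotype)`.  The shipped default
coefficients (β₀ = −17.52, β₁ = 17.55, β₂ = 14.17,
`src/phenoprio/data/combiner_default.json`) were fit once, with 10-fold
stratified cross-validation, on 10,000 + 10,000 labelled synthetic score
pairs from `make_combiner_training_set` (seeded; CV accuracy 0.98); any
two-column labelled set can be refit with `train_combiner`.  With the
phenotype prioritiser disabled the combined score *is* the genotype score
(variant-only analysis).  Genes are ranked per MOI by descending combined
score with tie-averaged midranks.

## Benchmark statistics

Causal ranks are binned as Top (exactly 1), 2–5, 6–10, >10, and Filtered
out/Not prioritized; a tie-averaged rank bins by its numeric value, so a
1.5 falls in 2–5 and Top remains reserved for an outright first place.
Rank summaries (mean/SD/median/min/max) are computed on the effective N
(sentinels excluded) while top-k percentages use the full N.

* **Cohen's kappa** on the 5×5 bin table, with the Landis–Koch verbal
  bands (<0 poor, ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80
  substantial, ≤1 almost perfect).  Percentage agreement is reported under
  both the all-patients and pairwise-numeric denominators, which differ
  whenever sentinels occur.
* **Stuart–Maxwell** marginal-homogeneity chi-square on the first k−1
  marginal differences; a singular covariance (an empty bin) is handled by
  the Moore–Penrose generalized inverse with df = rank.
* **Wilcoxon signed-rank**, two-sided, zero differences dropped, midranks
  on |d|; the null distribution is enumerated exactly (by convolution over
  doubled midranks, so ties are handled exactly) up to 25 informative
  pairs, and normally approximated beyond that with tie and continuity
  corrections — the continuity correction keeps the two branches within
  0.01 of each other at the crossover.

## Synthetic cohort generator

`make_cohort` emulates the structure of a solved rare-disease exome
cohort, deterministically under (spec, seed):

* solved-genotype mix 53.7% homozygous, 29.1% compound heterozygous, 9.7%
  heterozygous, 7.5% hemizygous, allocated by largest remainder (at
  n = 134 this is exactly 72/39/13/10); hemizygous patients are male with
  the causal gene on X;
* per-exome post-filter variant load drawn from a negative binomial
  (mean 474, dispersion 12) truncated to [229, 1276] — only the mean and
  range of the emulated load are constrained, so a moderate-dispersion
  count model is the least committal choice;
* 19 diagnosis labels, each with a fixed representative profile of 1–6
  deep terms from one branch of a 120-term, 6-branch synthetic ontology
  (≥4 levels, with diamond parents);
* each diagnosis carries two autosomal-recessive genes and one dominant
  gene (some also an X-linked gene), giving genetic heterogeneity; 5% of
  causal genes are "novel" (no human annotation; a mouse model and a
  0.9-confidence interaction edge to an annotated gene of the same
  disease carry the evidence);
* background variants are drawn from a shared 6,000-variant population
  pool (so allele frequencies are consistent across patients) with ~22%
  designed to fail a specific filter (common, removed consequence class,
  low quality, or non-PASS FILTER), and ~10% of passing alleles absent
  from every reference source;
* causal genotypes are spiked as rare loss-of-function or
  predicted-pathogenic alleles (10% whitelisted), and an optional
  mis-call corruption rewrites a homozygous/hemizygous causal call as
  heterozygous, which the inheritance filter then removes.

What the generator does **not** emulate: realistic human site-frequency
spectra, linkage structure, transcript-level annotation ambiguity,
cross-species ontology mapping (all species share one ontology), and
sequencing artefacts beyond the explicit corruption flags.  Passing the
end-to-end tests therefore demonstrates the internal consistency of the
pipeline and its qualitative behavior (phenotype evidence rescues ranking;
removing it degrades ranks; mis-called genotypes are filtered), not
clinical performance on real exomes, which depends on annotation-database
quality the synthetic knowledge base idealizes.

## Numerical and degenerate-input choices

* Frequencies are percent everywhere; cutoff comparisons are inclusive.
* Chromosome names are normalized by stripping `chr`; `M` ≡ `MT`.
* Multiallelic VCF rows are a hard error (decompose upstream); missing
  genotypes are skipped with a warning; a multi-sample VCF is rejected.
* Unresolvable profile terms are dropped with a warning; a fully
  unresolvable profile is an error.
* An empty post-filter variant set yields empty ranked tables, not an
  error.
* Kappa on a degenerate table (chance agreement 1) is defined as 1 when
  observed agreement is also 1, an error otherwise.
* The test-suite and acceptance cohort uses 50 patients at the default
  per-exome variant load, which exercises every pipeline stage at
  realistic scale while keeping the whole run in seconds.

## Known limitations

* The compound-heterozygote enumeration is phase-blind, so two variants on
  the same haplotype can form a (false) candidate pair.
* Only the best-matching disease's MOI is consulted for the penalty; a
  gene with both dominant and recessive disease entries can be penalized
  even when the recessive entry matches.
* The combiner coefficients are a synthetic-data stand-in; on real data
  they should be refit to a curated disease/benign training set.
* Preset pathogenicity values other than the in-frame 0.85 are defaults,
  not anchored constants.
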