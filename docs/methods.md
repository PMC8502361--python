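# Methods

## Problem setting

A pregnancy at risk for an autosomal recessive disorder: both parents are
heterozygous carriers of (usually different) pathogenic variants in the
same gene. Maternal plasma cell-free DNA is a mixture of maternal
fragments (proportion 1−f) and fetal fragments (f, the *fetal fraction*,
typically 5–28% in the first and second trimester). The diagnostic
question is which haplotype — pathogenic (P) or normal (N) — the fetus
inherited from each parent. Because the fetal signal is a small dosage
tilt spread over many SNPs, the analysis aggregates allele counts across
the ~2 Mb of highly heterozygous SNPs flanking the target gene (relative
haplotype dosage), which requires *phased* parental haplotypes.

## Direct phasing from linked reads

Instead of inferring phase from an affected sibling, haplotypes are read
directly from linked-read sequencing: high-molecular-weight molecules
(≥50 kb) are partitioned into barcoded droplets, so short fragments
sharing a barcode derive from the same molecule and hence the same
haplotype.

The phaser works on allele-level observations `(barcode, SNP, allele)`:

* **Evidence graph.** For every pair of heterozygous sites sharing a
  barcode, a cis count (equal alleles observed) and a trans count
  (opposite). Conflicting observations of one SNP within a barcode are
  resolved by majority, ties dropped. Pairs further apart than
  `max_pair_dist` (default 500 kb) are ignored — molecules rarely link
  beyond a few molecule lengths, and dropping distant pairs suppresses
  spurious evidence from barcode collisions (several molecules per
  droplet are expected and tolerated).
* **Greedy assembly.** Sites are scanned left to right; a site joins the
  current block when its net orientation evidence against the phased
  members reaches `min_margin` (default 2) with total support
  ≥ `min_support` (default 2) — two concordant barcodes, so a single
  erroneous observation cannot switch the phase. Otherwise a new block
  starts. Orientation ties (only possible with `min_margin=0`) defer to
  the nearest upstream phased site.
* **Block linking.** Blocks from different assemblies sharing ≥2 phased
  SNPs merge if the shared sites vote a consistent relative orientation;
  an exact 50:50 vote leaves them unmerged with a warning.
* **Anchoring.** The block containing the pathogenic site fixes the P/N
  labels (P carries the variant allele). A singleton block carries no
  linkage and cannot anchor. If no block covers the variant, phasing
  failed for that parent and its fetal allele is reported as
  not-applicable — the maternal and paternal analyses are independent, so
  the other parent's call survives.

Block statistics follow the standard conventions: spans are 1-based
inclusive, N50 is the length at which blocks of that size or larger cover
half the phased span.

Users with already-phased VCFs (pipe-separated GT plus PS tags) can
bypass this module entirely.

## cfDNA mixture model and HMM

For each parent separately, the hidden state at that parent's informative
SNPs is the fetal-inherited haplotype, P or N. Writing f for the fetal
fraction, the expected plasma fraction of the P-haplotype allele is the
mixture of maternal dosage (1−f) and fetal dosage (f), with the fetus
contributing half a genome from each parent:

| configuration | state P | state N |
|---|---|---|
| mother het, father hom for mother's P allele | (1+f)/2 | 1/2 |
| mother het, father hom for mother's N allele | 1/2 | (1−f)/2 |
| father het, mother lacks father's P allele | f/2 | ε |
| father het, mother carries father's P allele | 1−ε | 1−f/2 |

ε (default 0.005) absorbs sequencing error at sites where an allele would
otherwise be absent; all fractions are clamped to [ε, 1−ε] so every
emission stays possible. Emissions are binomial: P-allele reads out of
the SNP's depth at the expected fraction; a zero-depth SNP contributes
log-probability 0. Binomial emissions were chosen over a normal
approximation because plasma depths per SNP are modest (tens to a few
hundred reads).

Transitions between adjacent informative SNPs are recombination
fractions from a genetic map (piecewise-linear cM in bp, clamped outside
the anchored range) through the Haldane map function
r = (1 − e^(−2d/100))/2 — no crossover interference, r ≈ d/100 at small
distances. Kosambi is available by configuration. r is floored at 1e−8
so co-located SNPs never produce −∞ log-transitions. Decoding is exact
log-space Viterbi with uniform initial probabilities; backtracking ties
prefer the no-switch predecessor, biasing against spurious
recombinations and making the decoder deterministic.

### Genotype-call rules

The goal is the fetal genotype at the pathogenic site, not the whole
path. A decoded segment (maximal constant-state run, spanning the bp
interval from its first to last member SNP) "spans the gene" when it
fully contains the configured gene interval. Exactly one spanning
segment → that segment's state is the call, whatever the total number of
segments (a crossover outside the gene is harmless). No spanning segment
— a state switch between the SNPs flanking the gene, or informative-SNP
coverage that does not reach across the gene — → no-call. With more than
two segments the same unique-spanning-segment test applies, a
conservative extension of the two-segment rule.

### Confidence score

The CS estimates P(call is correct | design): `replicates` (default
1000) datasets are simulated under the *called* state — depths resampled
with replacement from the observed per-SNP depths (preserving depth
heterogeneity), counts binomial at the called state's expected fractions
— then re-decoded and re-called identically. CS = fraction of replicates
reproducing the call; CS < 0.99 (strict) is a no-call. The replicate
decoder is a vectorised batch Viterbi verified equivalent to the scalar
decoder, and the batch call rule is verified equivalent to the segment
rule. An alternative mode simulating under both states was considered
and rejected for the default: the design-only score matches the
practice of powering the call before conditioning on the observed
outcome. Note the call rules run *before* the CS: a boundary inside the
gene is a no-call even at CS = 1.

### Fetal fraction

At paternal-informative SNPs the paternal-specific allele fraction q is
≈ f/2 where the fetus inherited that allele and ≈ ε where it did not —
both modes are present because specific alleles sit on both paternal
haplotypes. Sites with depth < 50 or q > 0.4 (likely genotyping errors)
are excluded; the two modes are split by maximising between-class
variance over the sorted q values (an Otsu-style threshold, degenerate
splits falling back to all sites), and f = 2 × median of the signal mode
(mean available as an option; the median is robust to residually
mis-genotyped sites). An estimate of zero raises an error instructing
the user to supply f explicitly.

## Synthetic data

The generator emulates the targeted linked-read assay end to end:

* **Panel and parents** — n SNPs (default 300) uniform over a 2 Mb
  region; per-site heterozygosity 0.6 per parent; each carrier parent
  heterozygous at its configured pathogenic site, modelled as a biallelic
  marker (large deletions are represented abstractly the same way).
* **Molecules** — lengths exponential (mean 100 kb) truncated below at
  the 50 kb library floor (by memorylessness, a shifted exponential);
  each molecule copies one haplotype; covered SNPs are observed with
  probability 0.5; molecule count set so mean per-SNP observation depth
  ≈ the 100× target; 10 molecules share each barcode, so locus-level
  collisions occur and the phaser must tolerate them.
* **Fetus** — per parent, a uniform initial haplotype and map-driven
  crossovers between adjacent SNPs (the generative twin of the HMM
  transition model).
* **Plasma** — per-SNP Poisson depth (default 200×, configurable; cfDNA
  panels in this depth range are typical for targeted captures), each
  read maternal with probability 1−f or fetal with f, alleles equally
  likely within the source genotype, then flipped at the error rate
  (default 0.005). Counts are drawn binomially from the exact per-read
  alt probability, distributionally identical to per-read simulation.
* Fetal fraction defaults to 0.132, the validation cohort's mean, and is
  constant across SNPs (singleton pregnancy).

What it does **not** model: capture efficiency and GC bias, read-level
artifacts (the observations are allele-level), overdispersed plasma
depth (a negative-binomial option is the natural extension), maternal
mosaicism, twins. Passing tests therefore demonstrate the inferential
machinery under the stated mixture model, not robustness to assay-level
artifacts of real libraries.

## Validation battery and problem sizes

`haplonipt.validation` packages the experiments the test suite and
`scripts/acceptance.py` run; sizes were chosen to characterise each
property while keeping the whole battery around half a minute:

* Viterbi versus vectorised exhaustive enumeration: 100 random instances
  of ≤12 SNPs (agreement must be exact).
* End-to-end allele recovery: 200 simulated pregnancies at f = 0.10,
  200× depth, 100 informative SNPs per parent, no recombination,
  f re-estimated per pregnancy (≥99% required; at these settings the
  battery recovers 100%).
* Fetal-fraction bias: 50 pregnancies at 400× and 300 SNPs, error
  0.1% (|bias| < 0.005 required).
* CS calibration: 500 truth-known cases drawn over f ∈ (0.03, 0.20),
  depths {50, 100, 200} and {30, 60, 120} SNPs; among CS ≥ 0.99 calls
  the error rate must stay within 2× the nominal 1%.
* Recombination handling: deterministic constructed crossovers inside
  (→ no-call) and outside (→ correct two-segment call) the gene.
* Error-free, collision-free barcodes: phasing must reproduce the truth
  exactly up to a global flip per block.

The packaged cohort tables are transcriptions of a published 40-family
clinical validation and carry its printed precision: block spans agree
with the printed kb sizes at 0.1 kb, a few rows only at 0.1 kb exactly
(the source table's own internal rounding).

## Known limitations

* The greedy phaser is a deliberate simplification of production
  linked-read phasers; it is exact on clean data and its thresholds are
  conservative, but it does not perform global optimisation and its
  switch-error rate on noisy, collision-heavy data has no benchmark here.
* The gene must lie strictly within the informative-SNP span of a single
  segment to be callable; genes at the panel edge become no-calls.
* The X chromosome and de novo variants are out of scope (autosomal
  recessive inheritance only), as are structural-variant breakpoints —
  deletions enter as marker alleles.
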