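# haplonipt

Proband-free **noninvasive prenatal diagnosis (NIPD) of autosomal recessive
monogenic disorders** from maternal plasma cell-free DNA.

Couples who both carry a pathogenic variant (β-thalassemia, methylmalonic
acidemia, phenylketonuria, …) face a 1-in-4 risk of an affected fetus.
Relative haplotype dosage (RHDO) can read the fetal inheritance out of
maternal plasma, but classically needs a proband (an affected child) to
phase the parental haplotypes. This package implements the proband-free
alternative: parental haplotypes are phased **directly** from barcoded
linked-read sequencing of high-molecular-weight DNA, and the fetal
genotype is decoded from plasma allele counts with a hidden Markov model.

It is a library first (importable API plus `examples/`), with a thin
`haplonipt` CLI for shell use, and ships a synthetic-data generator so the
whole pipeline is testable without any sequencing data.

## The method

1. **Direct phasing** — short fragments sharing a gel-bead barcode come
   from the same long molecule, so their alleles at heterozygous SNPs are
   phase evidence (cis/trans counts per SNP pair). Blocks are assembled by
   greedy 2-coloring, linked via overlapping SNPs, and anchored at the
   pathogenic variant: the haplotype carrying it is **P** (pathogenic),
   the other **N** (normal). If no block covers the variant, that parent
   is a phasing failure and its allele cannot be called.
2. **Informative SNPs** — sites heterozygous in the mother and homozygous
   in the father power the maternal analysis; the mirror configuration the
   paternal one.
3. **Fetal fraction** *f* — at paternal-informative SNPs the allele absent
   from the mother appears at fraction *q ≈ f/2* when the fetus inherited
   it; *f* = 2 × median(*q*) over the signal sites.
4. **HMM / Viterbi** — hidden state: which parental haplotype (P or N) the
   fetus inherited at each informative SNP. Emissions are binomial in the
   P-allele read count with expected fractions from the cfDNA mixture
   (e.g. maternal-informative, father homozygous for P: (1+f)/2 under P,
   1/2 under N; paternal-informative: f/2 under P, ≈0 under N).
   Transitions are recombination fractions from a genetic map (Haldane
   map function, r = (1 − e^(−2d/100))/2 for d in cM).
5. **Call rules** — one decoded segment spanning the target gene gives its
   state; a haplotype-block boundary inside the gene gives a no-call.
6. **Confidence score (CS)** — replicate datasets are simulated under the
   called state at the observed depths and *f*, re-decoded and re-called;
   CS is the fraction reproducing the call, and CS < 0.99 is a no-call.

## Worked example

```bash
python examples/03_infer_fetal_genotype.py
```

prints (abridged):

```
estimated fetal fraction 0.137 (simulated truth 0.132)
maternal path: 62 informative SNPs, 1 segment(s)
paternal path: 81 informative SNPs, 1 segment(s)
fetal genotype category: CARRIER (P = inherited the pathogenic haplotype from that parent)
matches simulation truth: True
```

A simulated carrier×carrier family at the cohort-mean fetal fraction
(13.2%) and 200× plasma depth: the fetus inherited the normal maternal
haplotype and the pathogenic paternal one, hence a carrier call, with
confidence score 1.0 for both parents. The other examples cover the
simulator (`01`), barcode phasing and block statistics (`02`) and the
packaged 40-family validation cohort (`04`). The same steps are available
from the shell: `haplonipt simulate|phase|snps|ff|infer|report|run`.

## Validation cohort tables

`haplonipt.data` ships per-family tables transcribed from a published
40-family clinical validation (genotypes and fetal fractions; per-parent
anchoring phase blocks; NIPD calls with invasive-diagnosis ground truth).
`haplonipt.report` recomputes the cohort summaries from them: 78 parental
haplotypes determined, 38 fully-called families all concordant with
invasive diagnosis, 2 no-call families, 11 affected / 15 carrier /
12 normal fetuses.

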