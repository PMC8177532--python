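# Methods

This note documents the models behind `litterscan`, the defaults and why
they were chosen, and what the synthetic-data tests do and do not
demonstrate about real data.

## Problem setting

A female snake kept in isolation produces a litter. Two mechanisms can
explain it: fertilisation by long-term stored sperm (LTSS) or facultative
parthenogenesis (FP) by automixis. The package decides between them from a
mother + litter panel of biallelic SNP genotypes, and additionally
estimates the minimum number of sires. All analyses assume unlinked,
biallelic, autosomal loci and a correctly identified mother.

## Paternal-allele scan

At a locus where the mother is homozygous `a/a`, each egg receives `a`
from her, so any other allele in an offspring is paternal (or an error).
The scan evaluates exactly these loci and flags an offspring when its
genotype contains ≥ 1 non-maternal allele. At maternal *heterozygous* loci
no allele can be ruled non-maternal without phase, so they are excluded —
which is also why FP cannot be rejected from heterozygosity alone.

Two summaries are reported:

* **liberal count** — loci where any offspring is flagged; inflated by
  per-individual miscalls (rate analysis below);
* **conservative count** — loci where *all* offspring are flagged; a
  miscall-driven false positive here requires simultaneous errors in every
  offspring, with probability (2ε/3)^k for k offspring — about 10^-11 for
  k = 5 at ε = 0.01 — so any appreciable conservative count is genuine
  paternal signal.

**Missing-data policy.** Default `strict`: a locus with any missing
offspring call is excluded from the conservative set (a locus cannot claim
"all offspring flagged" when one was unobserved). The alternative
`evaluated_only` requires only that all *observed* calls are flagged.
Strict is the default because the conservative count's purpose is to be
unimpeachable; both are available and reported.

Multi-allelic observations at a maternal-homozygous locus count as
paternal evidence like any other non-maternal code.

## Reproductive-mode classifier

Per offspring, with paternal fraction *f* (flagged / evaluated loci) and
heterozygosity *H* over non-missing genotypes:

* **sexual** if *f* ≥ `sexual_min_fraction` (default 0.05);
* **parthenogen** if *f* ≤ `parthenogen_max_fraction` (default 0.04) and
  *H* ≤ max(`max_het_ratio` × *H*<sub>mother</sub>, `het_floor`)
  (defaults 1.0 and 0.05);
* **ambiguous** otherwise.

The litter is LTSS iff at least one offspring is sexual (one proven
paternal contribution proves stored sperm was used), FP iff every
offspring is parthenogen. An all-male litter is reported as corroborating
FP (ZW taxa produce only ZZ parthenogens) but never suffices.

**Why these thresholds.** They are derived from the error model, not
fitted. Under a symmetric miscall channel at rate ε, a parthenogen's
expected *f* is 2ε/3 (its own miscalls) plus leakage from maternal
miscalls (a heterozygous mother read as homozygous admits a truly maternal
allele as a "paternal" flag; a homozygous mother read as the opposite
homozygote flags every offspring). At ε = 0.01 and realistic allele
frequencies this totals ≈ 0.012. A sexual offspring's *f* is the
probability its sire transmitted a non-maternal allele at a
maternal-homozygous locus — `pq/(p² + q²)` at reference frequency `p`,
i.e. ≥ 0.1 for p ∈ [0.1, 0.9] and ≈ 0.32 averaged over the simulator's
default frequency spectrum. The pair (0.04, 0.05) therefore sits ≥ 4
Poisson standard deviations above the parthenogen expectation (at ≥ 300
scanned loci) and ≥ 9 binomial standard deviations below the sexual
expectation. The heterozygosity bound uses the fact that automixis can
never raise *H* above the mother's; the absolute floor 0.05 absorbs
error-induced heterozygosity when the mother is nearly homozygous. For
panels with substantially noisier genotyping than ε ≈ 0.01, widen the
margins accordingly.

## Sibship likelihoods and the minimum sire count

For offspring pair (i, j) at a biallelic locus with alt-allele frequency
q, the mother's genotype is taken as known and the father's is integrated
out under Hardy–Weinberg (p², 2pq, q²):

* full-sib: `L_FS = Σ_F HWE(F) · A_i(F) · A_j(F)`
* half-sib: `L_HS = [Σ_F HWE(F) · A_i(F)] · [Σ_F HWE(F) · A_j(F)]`

where `A_k(F) = Σ_T P(T | mother, F) · P(obs_k | T)` sums Mendelian
transmission over the true genotype T, and the observation channel is
`P(obs | T) = (1 − ε)·1[obs = T] + ε/3` (a symmetric uniform-replacement
error at rate ε, matching the single per-SNP error-rate convention of
pedigree-reconstruction software; default ε = 0.05). Loci are treated as
independent; the LLR is the summed per-locus log ratio. Offspring pairs
with LLR ≥ `llr_threshold` (default 0, ties joined) are linked and
connected components form the paternal full-sibships; the component count
is the minimum sire count. This is a deliberate simplification of full
pedigree MCMC: it produces the full-sib grouping and minimum sire count
only, not a pedigree posterior.

Numerical details: allele frequencies are counted over *all* samples
including the mother (a tiny-sample design choice; it slightly biases
frequencies toward the family and is documented rather than corrected);
monomorphic loci are skipped (their likelihood ratio is exactly 1);
loci made impossible under both hypotheses at ε = 0 are skipped rather
than propagating −∞; the pair is internally ordered by sample index so the
LLR is exactly symmetric in floating point.

**High-MAF locus selection.** The replication profile feeds the sibship
stage loci with within-panel MAF ≥ 0.4 rather than exactly 0.5.
Conditioning a six-sample panel on *perfectly balanced* allele counts is
an ascertainment that selects loci where the sibs look maximally
dissimilar; empirically it drives all pairwise full-sib LLRs negative even
for true full sibs, while joint pedigree reconstruction over the whole
litter tolerates it. A MAF ≥ 0.4 band keeps the intent — maximally
informative loci — without the degenerate conditioning (single-sire
recovery 20/20 seeds at ≥ 0.4 or ≥ 0.3; 0/20 at ≥ 0.5).

## Litter simulator

The simulator emulates a mother + litter SNP panel:

* **Parents** — per-locus reference-allele frequencies, default uniform on
  [0.1, 0.5] (a reduced-representation SNP panel ascertained for
  variability); parents drawn under Hardy–Weinberg. Allele codes 1/2.
* **LTSS litters** — each offspring receives one uniformly chosen maternal
  allele and one from its assigned sire (1..k sires, default 1, assignment
  random or explicit); sex is Bernoulli (default ratio 0.5).
* **FP litters** — gametic duplication: homozygous everywhere for one
  maternal allele. Terminal/central fusion: maternal homozygous loci are
  copied; heterozygous loci stay heterozygous with probability
  `het_retention`, default 0.1 (terminal-fusion-like; set ≈ 0.7 for
  central fusion), else become homozygous for a uniformly chosen maternal
  allele. All FP offspring are male. A single retention probability stands
  in for the recombination-distance dependence of real automixis; only the
  qualitative homozygosity signature is modelled.
* **Error overlay**, in order per cell: missingness (default 0.01), then
  allelic dropout of heterozygotes (default 0.01), then miscall to a
  uniform draw from the three biallelic genotypes (default 0.005). The
  order mirrors the physical process (no call ≻ partial signal ≻ wrong
  call) and keeps expectations computable. The dropout/miscall defaults
  are plausible ddRAD magnitudes chosen for power studies, not measured
  values. Randomness is keyed per sample id, so the overlay commutes with
  sample reordering; everything is byte-deterministic under a seed.
* Infertile-ova counts are carried as litter metadata only (no genotypes).

What passing tests show about real data — and what they do not: the
simulator has no linkage, no null alleles, no locus- or
individual-specific error rates, no population structure and no mutation.
Against real panels the scan's *conservative* statistic is the robust
quantity; per-offspring fractions and the classifier margins should be
re-examined if genotyping error departs strongly from the modelled rates.

## In-silico ddRAD digest

Complete double digest with PstI (`CTGCA^G`) and MspI (`C^CGG`):
all top-strand occurrences are cut (both defaults are palindromic;
non-palindromic enzymes are additionally scanned as their reverse
complement with the mirrored offset). Coordinates are 0-based half-open;
fragment lengths always sum to the sequence length; if two cuts coincide
the first enzyme's label wins (documented tie-break; impossible for the
default pair). Size selection keeps lengths in [center − halfwidth,
center + halfwidth], inclusive — "300 ± 50 bp" read literally as
[250, 350] — optionally restricted to mixed PstI/MspI ends, the class a
ddRAD library sequences. Methylation sensitivity and partial digestion are
not modelled.

## Problem sizes used in the test and acceptance suites

Closed-form checks use 20,000-locus single-litter simulations (Monte-Carlo
SE ≈ 0.001 on the (1/2)^5 = 0.03125 conservative fraction); the mode-
recovery grid uses 200 litters of 500 loci; sibship recovery uses 100
litters each of one and two sires (8 offspring, 400 loci at allele
frequencies in [0.3, 0.5], ε = 0.05); the replication-profile run uses a
4,000-locus panel, matching the scale of real ddRAD mother+litter panels;
digest checks use synthetic sequences up to 200 kb. All are sized so
three-standard-error bands are decisive.

## Known limitations

* The scan cannot attribute paternal alleles at maternal heterozygous loci
  (needs phase) and does not attempt to identify the father.
* The pairwise sibship stage is not a pedigree sampler: with very few or
  low-information loci it degrades by splitting true sibships (each
  offspring its own cluster), and transitive linking can merge clusters a
  joint analysis would keep separate.
* Allele frequencies estimated from the family itself are biased toward
  the family's alleles; with external population frequencies available,
  pass them explicitly.
* The classifier's defaults presume panels of ≥ a few hundred scanned loci
  and genotyping error ≲ 1–5%; outside that regime, set thresholds from
  the error analysis above rather than relying on defaults.
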