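# Methods

## Model

Each SNP is treated as an independent biallelic locus segregating through a
known pedigree. For an individual with genotype g ∈ {0, 1, 2} (copies of
the allele coded 1):

* **Founder prior.** Founders — and "phantom" founders materialised for
  every unknown parent of a non-founder — follow Hardy–Weinberg
  proportions ((1−p)², 2p(1−p), p²) at the reference allele frequency p.
* **Transmission.** A parent of genotype g transmits the allele 1 with
  probability g/2; the offspring genotype is the sum of the two transmitted
  alleles. This single-locus Mendelian kernel T(g_o | g_s, g_d) is the only
  genetic model used: no linkage, LD or haplotype information enters.
* **Penetrance.** Observed genotypes are assumed error-free, so the
  penetrance is an indicator of the observed code (uninformative for
  missing genotypes). Genotyping-error modelling is out of scope.

### Iterative peeling

Genotype probabilities are computed by anterior/posterior message passing
on the mating graph. The *anterior* of an individual integrates everything
above it: a transmission-weighted sum over the parents' genotype pairs,
each parent represented by anterior × penetrance × the posteriors of all
its *other* matings, and each full sib of the focal individual contributing
its own evidence inside the sum. The *posterior* sent to a parent from one
mating marginalises the mate and that mating's offspring in the same way.
The final triplet is anterior × penetrance × product of mating posteriors,
normalised per individual and SNP.

All quantities are iterated to a fixpoint (tolerance 1e-6 on any stored
probability, at most 30 rounds by default). On loop-free pedigrees the
fixpoint equals exact marginalisation — verified against brute-force
enumeration of all genotype configurations on random pedigrees of up to 12
individuals (agreement < 1e-6). On looped pedigrees (inbreeding loops,
cross-mated families) iterative peeling is the standard approximation;
non-convergence raises a warning and returns the current state.

Before peeling, a deterministic pass applies the hard Mendelian rules
(a homozygous parent forces one allele in each offspring; both homozygous
parents force the genotype; a homozygous offspring forces one allele in
each parent) to a fixpoint. It doubles as a consistency check: impossible
observed genotypes raise an error naming a trio on the conflict.

### Numerical choices

Products of many posterior factors (a popular sire can appear in hundreds
of matings) are accumulated in log space with an exact count of zero
factors per genotype state, so exclusion of one factor never divides by
zero and long products cannot underflow. Probabilities are renormalised at
every step. Hard calls are made only when the top posterior probability
reaches the calling threshold *and* strictly exceeds the runner-up; with
the default threshold 0.98 a tie can never be called, and everything below
threshold is reported as "not imputed" (code 9) while the dosage
p₁ + 2p₂ is always retained. The reference allele frequency is the mean
observed code / 2 over the reference set, clamped to
[1/(2n_ref + 2), 1 − 1/(2n_ref + 2)] so that a SNP fixed in a finite
reference never zeroes out genotype states elsewhere.

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `call_threshold` | 0.98 | posterior needed for a hard call; accuracy metrics use dosages and are insensitive to it |
| `max_rounds` / `tolerance` | 30 / 1e-6 | fixpoint iteration control |
| `frequency_clamp` | 1/(2n_ref+2) | floor/ceiling on the founder-prior allele frequency |

## Accuracy metrics

The animal-specific accuracy is the Pearson correlation over SNPs of
(true genotype − mean gene content) with (dosage − mean gene content),
where mean gene content 2p is the per-SNP average genotype code of the
scenario's genotyped reference — never of the truth. Subtracting it
removes the between-SNP variance created by allele-frequency differences;
the raw ("uncorrected") correlation keeps that common component and is
inflated, most strongly when imputation is poor. For the parent-average
predictor the corrected accuracy tends to √0.5 ≈ 0.71 for any allele
frequency spectrum, while the raw accuracy depends on the spectrum (≈ 0.88
under the calibrated spectrum below). Correlations with zero variance in
either argument are flagged undefined and excluded from group means rather
than zero-filled, which would bias monomorphic edge cases. Aggregates pool
animal × replicate values; per-SNP accuracies are additionally averaged in
20 equal-width MAF bins on [0, 0.5] as a deterministic substitute for a
smoothed curve.

## Synthetic data

The generator emulates the structure of a historical dairy-cattle
feed-intake study: ungenotyped test cows, each the daughter of a genotyped
sire (drawn from a small sire pool) and an ungenotyped dam who is herself
the daughter of a genotyped maternal grandsire; per cow up to four
genotyped offspring whose sires are drawn without replacement (within cow)
from a pool of ungenotyped mate sires shared across all cows; and a large
genotyped base reference unrelated to the cows, which anchors the
allele-frequency and mean-gene-content estimates exactly as the study's
reference population does. Defaults are the study's scale: 805 cows, 60
mate sires, 4 offspring per cow, a base reference of 4000. The
shared mate-sire pool matters: with one genotyped offspring per cow each
mate sire has ~13 genotyped offspring, so peeling effectively genotypes
the mates and the offspring then act almost like direct gamete reads of
the cow — which is why empirical accuracies beat the selection-index
predictions once offspring are genotyped.

Founder haplotypes come from one of two models:

* **coalescent** (msprime): one population with piecewise-constant
  effective size 100 now, 1256 at 1000 years, 4350 at 10 000 years and
  43 500 at 100 000 years, a generation interval of 5 years to convert
  years to generations, mutation rate 2.5e-8 per site (binary model) and
  recombination 1e-8 per bp (100 cM over the full-scale 1e8 bp
  chromosome). 2000 segregating sites are sampled uniformly, without MAF
  filtering; the resulting mean minor-allele frequency is ≈ 0.22 and the
  spectrum is mildly U-shaped. The default sequence length is 5e7 bp; the
  short-length regime is noisy because the recent bottleneck leaves few
  deep lineages per genealogy, so means are reported over ≥ 3 replicates.
* **sfs** (default for accuracy experiments): per-SNP allele frequencies
  drawn from Beta(b, b) with b = 0.8149, calibrated once so that
  E[min(p, 1−p)] = 0.23 matches the coalescent mode, with haplotype
  alleles sampled independently per site. Because the imputation method is
  strictly single-locus, only the frequency spectrum matters and this mode
  is statistically equivalent for every accuracy reported here, at a
  fraction of the cost. A point-frequency option exists for degenerate
  checks.

Gene drop assigns two pool haplotypes per founder (without replacement
while the pool lasts) and one recombinant gamete per parent to every
non-founder: crossover counts are Poisson with mean 1 per 100 cM
(Haldane, no interference), positions uniform, starting strand a fair
coin. An unknown parent contributes a fresh pool haplotype. SNP map
positions are drawn uniformly on [0, 100] cM rather than from physical
coordinates; all reported metrics are map-agnostic. Phase and crossovers
are recorded so tests can verify every gamete is a mosaic of exactly the
two parental gametes.

What the generator does **not** emulate: the real 14 733-individual
pedigree with its web of extra genotyped relatives (paternal half-sib
families, genotyped sons of the grandsires), genotyping errors,
non-random mating and selection, sex chromosomes, and per-SNP missingness
inside the reference. Passing tests therefore show that the method and
metrics behave as designed under the stated family structure, not that
real-data accuracies would be identical — with the one caveat that the
extra relatives in real data can only add information, so the synthetic
scenario accuracies are, if anything, slightly conservative at zero
offspring.

## Selection-index predictions

Gene content is a heritability-1 trait, so the accuracy of its best linear
prediction from genotyped relatives is r = √(G′P⁻¹G) with P the additive
relationship matrix among the sources (diagonal 1 + F) and G the
source–candidate relationships. P is factorised by Cholesky; a
non-positive-definite P (duplicated or linearly dependent sources) is an
error, and an empty source set yields r = 0. The standard prediction grid
assumes mutually unrelated non-inbred parents, maternal half-sib offspring
with unrelated ungenotyped mates, and a dam who is a daughter of the
maternal grandsire; symmetric configurations (sire ↔ dam) share a row.

## Problem sizes used in the checks

The replicated scenario comparison runs a scaled design preserving the
study's ratios: 200 test cows, 15 mate sires, 15 genotyped sires, 15
maternal grandsires, 1000 base-reference animals, 500 SNPs and 3
replicates; the parent-average experiment uses 40 independent trios at
2000 SNPs; the coalescent spectrum check uses 4000 haplotypes on 5e7 bp in
3 replicates. Every random stage is driven by named substreams of one base
seed, so runs are bit-reproducible.

## Known limitations

Looped pedigrees receive approximate (fixpoint) probabilities; multilocus
peeling, long-range phasing and haplotype-library imputation are out of
scope, as is genotype-error-tolerant penetrance. The per-category accuracy
of the rare categories (Dam, DamPGS, Other) is not exercised by the
default generator, which links every cow through sire and maternal
grandsire unless `frac_cows_with_genotyped_ancestors` is lowered.
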