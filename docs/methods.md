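# Methods

This note documents the statistical procedures implemented in
`transheight`, the synthetic data that exercises them, the numerical
choices made where the design was open, and what the tests do and do
not establish about real data.

## Study design being modelled

The package reproduces the analysis skeleton of a two-population
(trans-ethnic) GWAS of a quantitative trait: per-study association on
covariate-adjusted Z-scores, fixed-effect meta-analysis with genomic
control, a group-level replication test of loci discovered in a source
population (European-like, "EUR") within a target population
(African-like, "AFR") whose LD structure differs, LD-based fine-mapping
of each locus, local-ancestry conditional and stratified models in an
admixed cohort, and a cis-eQTL enrichment comparison between the
original and the fine-mapped SNP lists.

## Association model

Heights are residualized by ordinary least squares on sex, age,
disease status and any further covariates, then standardized to
Z-scores (mean 0, sample SD 1 with the n-1 denominator):
`z = (r - mean(r)) / sd(r)`.  Each SNP is tested additively,

    z_i = b0 + beta * g_i + c' x_i + e_i,

with `g` the 0/1/2 allele count (males on an X-linked chromosome are
coded 0/2) and `x` the covariates.  The per-SNP P-value uses the normal
reference when n > 200 and the t reference below that; the studies
modelled here have n >= 386 where the two are indistinguishable.
Missing genotypes are dropped per SNP (complete case), with N recorded.
In admixed cohorts a global-ancestry covariate (here the individual's
mean European dosage, standing in for principal components) is included
in the SNP model; without it, any trait with ancestry-correlated
genetic effects shows genome-wide overdispersion that median-based
genomic control cannot repair (it rescales the median, not the tail).

Conditional models include the SNP genotype and the local-ancestry
dosage jointly and report both terms; exact collinearity is flagged and
the terms marked not estimable rather than raising.  Stratified
analysis fits the SNP model within each European-dosage stratum
{0, 1, 2}, skips strata below 50 individuals (logged), and combines the
remainder by inverse-variance weighting.

## Meta-analysis and genomic control

The fixed-effect inverse-variance combination uses weights
`w_i = 1/SE_i^2`:

    beta = sum(w_i beta_i) / sum(w_i),   SE = (sum w_i)^(-1/2),

with Cochran's `Q = sum w_i (beta_i - beta)^2` referred to chi-square
on k-1 df and `I^2 = max(0, (Q - (k-1))/Q) * 100` (0 when k = 1).
Genomic control converts two-tailed P-values to 1-df chi-square
quantiles and takes `lambda = median(chi2)/0.4549`; correction divides
the chi-square by lambda (equivalently multiplies SE by sqrt(lambda))
and never deflates when lambda < 1.  The pipeline applies GC twice —
per study before combination and once more on the combined statistics —
as two explicit steps.  QQ confidence bands are the 5th/95th
percentiles of each uniform order statistic across simulated null sets
of the same size.

## Replication framework

Loci known from the source population are tested for group-level
replication in the target meta-analysis:

1. **Proxy expansion.** Each index SNP is expanded to all common
   (MAF >= 0.05) source-panel SNPs with r^2 >= 0.8 within +/- 1 Mb.
   LD is computed from phased haplotype counts: `D = p_ab - p_a p_b`,
   `r^2 = D^2 / (p_a q_a p_b q_b)`.  The MAF floor matters: in any
   finite panel, near-singleton variants sharing one carrier haplotype
   are in perfect mutual LD across unrelated loci and would otherwise
   chain into arbitrarily large spurious proxy sets.  Each proxy's
   trait-increasing allele is predicted from phase (the allele with
   D > 0 to the index increasing allele); proxies with D = 0 are
   dropped and tallied, and a locus whose index is monomorphic in the
   panel is recorded as unresolvable.
2. **Binning.** A locus's proxies are clustered with target-population
   LD: the list is shuffled (to avoid bias toward significance), the
   first unbinned SNP becomes a bin index and absorbs all remaining
   SNPs with r^2 >= 0.3 to it, until the list is exhausted.  Bins
   partition the proxy list.
3. **One-tailed conversion.** Each bin is represented by its index
   SNP's one-tailed P: `P/2` when the observed effect direction matches
   the phase prediction, else `1 - P/2` (0.5 at beta exactly 0).
4. **Counting and the permutation null.** The replication metric is
   the number of bins with one-tailed P <= 0.05 summed over loci.  Its
   null distribution comes from sets of pool SNPs matched to the index
   loci on source-population MAF (tolerance +/- 0.02, widened stepwise
   to 0.05 when a locus has too few candidates; every widening is
   logged) and mutually quasi-independent (pairwise r^2 < 0.2, checked
   within the +/- 1 Mb window where non-trivial LD lives).  The
   empirical P is `#(null >= observed)/N` — the k/N convention, which
   reproduces 1/5819 = 1.7e-4 at the printed precision, whereas
   (k+1)/(N+1) does not — reported as "< 1/N" when no null set reaches
   the observation.  Null index SNPs receive a random increasing
   allele: under the null the one-tailed P is uniform for any
   orientation rule, so this choice cannot affect calibration.
5. **Fine-mapping.** The binning is repeated with SNPs processed in
   ascending one-tailed P (ties broken by genomic position, then id);
   the first bin's index is the locus's best-supported SNP, flagged
   against the 0.05/m Bonferroni threshold when the number of loci m
   is supplied.

## cis-eQTL enrichment

For a SNP list, the joint fraction is the share of members with trait
P < 0.05 and best cis-eQTL P < 0.01; members missing from either
lookup stay in the denominator (conservative).  The enrichment of the
fine-mapped list is referred to the joint fraction of frequency-matched
simulated sets (re-matched per list), with the same k/N empirical P and
below-resolution reporting.  The allelic-expression machinery that
produces the per-SNP eQTL P-values is consumed as an input table, not
re-implemented.

## Synthetic data generator

No deposited data accompany the study design, so every stage runs on
synthetic inputs whose structure mirrors phased HapMap-style panels and
admixed African-American cohorts.

**Panels.** The chromosome is a sequence of LD blocks with
exponentially distributed lengths (default mean 20 kb, variants every
1 kb).  Per block, an ancestral frequency is drawn uniformly from
(0.1, 0.9); each variant receives a shared per-variant jitter around it
(Balding-Nichols with F = 0.05) — without this, long blocks degenerate
into runs of identical columns whose proxy sets are unrealistically
large.  Population frequencies then follow the Balding-Nichols Beta
model around the per-variant ancestral value.  Eight founder haplotypes
per block carry alleles thresholded from a Gaussian copula (latent
correlation 0.85) whose random draws are shared between the two
populations, so the no-divergence limit yields identical panels;
haplotypes copy one founder per block.  This gives high within-block
r^2 (median pairwise ~0.6, with a realistic share of r^2 >= 0.8 pairs),
near-zero between-block r^2, and population-specific LD (the same block
can be tight in EUR and fragmented in AFR).

Because the realized two-population Fst of this generator is roughly
half the Beta parameter plus founder- and haplotype-sampling terms, the
`divergence_F` parameter is defined as the *target realized Fst* and
inverted through a measured monotone lookup table (13 grid points,
averaged over 3 seeds at 10,000 variants x 400 haplotypes with default
settings).  The default target 0.15 matches genome-wide CEU/YRI
differentiation; requested targets above the table's range (~0.33) are
rejected.

**Admixed cohorts.** Each chromosome copy is a mosaic of panel
haplotypes with exponential tract lengths and per-tract African origin
probability `admixture_alpha` (default 0.8).  The default tract mean is
1 Mb on the default 5 Mb chromosome: what carries over from real
admixed genomes (~10 Mb tracts from admixture ~8 generations ago on a
3,000 Mb genome) to a truncated synthetic chromosome is the
tract-to-chromosome ratio, i.e. how quickly local ancestry decorrelates
along the sequence, not the absolute tract length.  Genotype is the
sum of the two copies; the European-chromosome count per variant is
recorded as the local-ancestry truth (inference of local ancestry is
out of scope — the truth is consumed directly).  Males on an X-linked
chromosome carry one copy with doubled allele count.

**Phenotypes.** `height = 170 + 6*(sum_j beta_j g_j + noise) + 7*sex
- 0.05*(age-45) - 1*disease` cm.  With `heritability_target` unset the
noise is standard normal and betas are read as Z-units per allele;
when set, the noise is scaled so the realized genetic variance fraction
matches the target (a target of 1, or a positive target with no causal
effects, is rejected).

## Replicate-level experiments

`transheight.experiments` runs the full pipeline (phenotype draw ->
per-study scan -> GC -> IVW meta -> GC -> proxy/bin/one-tail/count ->
matched-null empirical P) across many replicates over one fixed pair of
panels and one cohort, sharing the LD caches.  Problem sizes: panels of
4,000 variants (6,000 for the power experiment) x 400 haplotypes, a
2 x 1,000-individual cohort, 100 index loci, 200 matched null sets.

Two deliberate desk-scale devices:

* **Effective sample size.** Planted effects are scaled by
  `sqrt(n_effective / n_actual)`, which preserves each SNP's
  non-centrality and the LD propagation of its signal while keeping the
  cohort small.
* **Tract length.** The experiment cohort uses 0.4 Mb tracts on a
  4-6 Mb chromosome so that local ancestry decorrelates along the
  chromosome roughly the way 10 Mb tracts do on a full genome.  With
  tracts as long as the simulated chromosome, every
  frequency-divergent SNP shares the causal loci's ancestry axis and
  the scan is confounded beyond what a global-ancestry covariate or
  genomic control can absorb — an artifact of truncating the genome,
  not a property of the method.

Under the global null the index list is drawn by the same matched-set
sampler as the null sets (targets sampled from the pool's MAFs), making
observed and null counts exchangeable by construction; the calibration
experiment checks that empirical P <= 0.05 occurs for ~5% of
replicates.  The power experiment plants effects of 0.05-0.10 Z units
(effective n = 20,000) at 40 of the 100 loci with the increasing allele
known, and expects empirical P <= 0.01 in >= 90% of replicates.

## Numerical choices and degenerate inputs

* Positions are 1-based inclusive bp (VCF convention); alleles are on
  the forward strand.  Strand-ambiguous A/T and C/G records are
  oriented by allele frequency and dropped when the effect-allele
  frequency lies in (0.42, 0.58).
* `fst_two_pop` weights the two populations equally; this reproduces
  the printed 0.701 from (0.85, 0.02).  H_T = 0 returns Fst = 0.
* P = 0 inputs to the lambda estimator are clipped to the smallest
  positive float and logged; empty inputs raise.
* The Z-score transform requires >= 2 individuals and non-constant
  residuals; collinear covariates raise.  Monomorphic SNPs are omitted
  from scans (logged), never raised.
* Matched-set assembly retries a set up to 20 times before failing
  loudly; candidate rejection uses precomputed neighbour sets, so
  generation is O(set size) per set after the first pass.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` substreams; identical config + seed
  reproduce outputs byte for byte.

## What passing tests do and do not show

The synthetic generator reproduces the *structural* features the
methods depend on — divergent allele frequencies with a controllable
Fst, block LD that differs between populations, admixture tracts with
known local ancestry, additive phenotypes — but not realistic
recombination maps, selection, relatedness, genotyping error, or
imputation uncertainty.  Calibration and power results therefore
establish internal correctness of the pipeline (type-I error control
and sensitivity under the stated generative model), not performance on
any particular real cohort.  The printed worked examples (combined
effect sizes, Fst, one-tailed conversions, permutation P resolution)
are exact arithmetic checks independent of the generator.

## Known limitations

* Fixed-effect meta-analysis only; no random-effects or
  sample-size-weighted variants.
* Local ancestry is consumed as truth; no inference (HAPMIX-style) is
  provided.
* The candidate pool for matched sets must be supplied (or defaults to
  common source-panel SNPs); the original analysis's exact pool
  definition is not recoverable from the text.
* Fine-mapping is purely LD/P-ranking based; no Bayesian credible sets.
* The divergence calibration table is measured at the default generator
  settings (8 founders, latent correlation 0.85, ancestral frequencies
  in (0.1, 0.9)); strongly different settings shift the realized Fst by
  a few hundredths.
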