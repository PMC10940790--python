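# Methods

This note documents the statistical models behind `poolscan`, the
defaults and why they hold, what the synthetic generator does and does
not emulate, and the places where the design was genuinely open.

## Coordinates and interval arithmetic

All coordinates are 1-based and inclusive. Interval length is defined as
`end − start` (not `end − start + 1`): that convention reproduces the
conventional printed sizes of the herring divergence loci exactly
(e.g. Chr15:6,750,000–7,000,000 → 250 kbp; Chr8:23,040,136–30,729,461 →
7,689,325 bp ≈ 7.7 Mb). BED input is 0-based half-open and converted on
read.

## Pool allele frequencies and n_eff

A pooled read sample of depth RD from a pool of n = 2N chromosomes has
frequency-sampling variance approximately p(1−p)(1/n + 1/RD). The
effective chromosome count

    n_eff = (n·RD − 1) / (n + RD)

satisfies 1/n_eff ≈ 1/n + 1/RD, is bounded by min(n, RD), increases in RD
and tends to n as RD → ∞. Raw counts are rescaled by n_eff/RD and kept
real-valued (rounding would bias low-coverage cells). Rescaling cancels in
the frequency ratio alt/(ref+alt); it matters only through n_eff in
estimators that charge sampling error.

SNP filters follow the standard pool-seq recipe, in a fixed order:
per-pool coverage mask outside the pool's [5th, 99th] percentiles
(computed over all SNPs before any masking, linear interpolation — the
quantile method is a package choice), then missing rate < 20%, minimum
minor allele count of 2 (counted in raw reads summed over pools; whether
to count in rescaled units was open, raw reads are the simplest auditable
choice), then polymorphism. With MAC ≥ 2 satisfied the polymorphism rule
is usually vacuous but it is kept as an explicit, separately tallied rule.

Marker partitions use the standard deviation of minor-allele-polarised
frequencies across pools (ddof = 1): undifferentiated 0.03 < SD ≤ 0.09
(boundary inclusive), differentiated SD ≥ 0.2, everything else in neither
set. Using alt-allele SD would be orientation-dependent. Thinning keeps
one SNP per window (1 kbp / 10 kbp), taking the first SNP by position in
each window anchored at the chromosome origin — deterministic and
independent of processing order; keeping the highest-SD SNP instead would
couple the partition to the statistic being studied.

## Pairwise pool-FST

The estimator is the two-sample Weir–Cockerham analysis of variance on
allele frequencies with the haploid sample size replaced by n_eff:

    MSP = Σ_i n_i (p_i − p̄)²,   MSG = Σ_i n_i p_i(1−p_i) / (Σ_i n_i − 2),
    n_c = Σ n_i − Σ n_i² / Σ n_i,
    θ̂  = Σ_loci (MSP − MSG) / Σ_loci (MSP + (n_c − 1) MSG).

Multi-locus estimates are ratios of sums, may be slightly negative under
no differentiation, and are floored at zero only for reporting. Because
n_eff charges both sampling layers, the estimator is unbiased when pools
are independently drawn and sequenced; feeding it two *identical* count
columns (which no sampling model produces) yields the expected small
negative value −1/(n_c − 1). An identity-based pool estimator would give
numerically different (cross-checked, not bit-compared) but equivalent
recovery on simulations; the ANOVA form was chosen because every
component is hand-computable in tests.

## dAF scans and divergence islands

dAF is the absolute difference of unweighted group means of pool
frequencies, pairwise-complete (weighting pools by n_eff was open;
unweighted keeps the statistic independent of depth differences between
pools). The rolling mean is SNP-count based, centred, over 100 SNPs,
never spanning chromosomes; chromosome ends use shrunken windows down to
50 SNPs, shorter stretches are missing.

dAF has no native p-value. The genome-wide significance line is
implemented as a two-sided Pearson chi-square (1 df) on n_eff-rescaled
allele counts summed per group, Bonferroni-corrected at α = 0.05 over the
SNPs tested; the smallest dAF among significant SNPs is reported as the
line-height analogue. This test assumes exchangeable pools within groups:
between-pool drift (island-model F > 0) inflates it, so the calibration
holds under weak structure (it is verified at F = 0.001) and the line
should be read as a screening device, not an exact test, when F is large.

Island detection is deliberately simple and fully exposed: outlier SNPs
(dAF ≥ 0.55 by default, the novel-outlier threshold; 0.4 for close-up
tracks) are clustered per chromosome, merging neighbours ≤ 100 kbp apart,
discarding clusters with < 5 outliers, reporting first-to-last outlier
span. The merging rule is a package choice — the source analyses report
islands without stating one — and the defaults cleanly recover a planted
200-SNP locus in simulation.

## Diversity windows

Each pool's sites are subsampled without replacement to a uniform depth C
(default: the 5% quantile of the pool's coverage; minimum 4) by a seeded
hypergeometric draw; sites below C are masked, sites whose minor count
falls below 2 after subsampling are treated as monomorphic. The C
retained reads are then treated as C sampled chromosomes — the standard
pool-seq approximation; the pool-size-aware corrections of pileup-based
tools are not reproduced, since only read counts (not pileups) enter this
package. Per segregating site h = 2k(C−k)/(C(C−1)); window π divides Σh
by the number of covered positions; Tajima's D uses the classical
constants at sample size C, requiring ≥ 3 segregating sites and a
positive variance estimate. Windows are 10 kbp with 2-kbp steps; windows
with covered fraction < 0.5 are missing. The covered fraction comes from
a per-position coverage track when one is supplied; otherwise the
fraction of unmasked SNP sites in the window serves as a density proxy
(exact invariant-site coverage is unknowable from a SNP table — this
fallback is documented precisely because it is weaker).

## Structural variants

Karyotype calling is not specified by the analyses this package
reimplements (they cite prior work), so a transparent, testable stand-in
is used: PCA of region dosages, k-means (k = 3) on PC1, clusters ordered
by mean dosage (AA lowest), per-individual silhouette as confidence. If a
cluster is empty or the mean silhouette falls below 0.7 every call is
flagged low-confidence — k-means on unstructured 1-D data plateaus near
0.6 while true karyotype clusters exceed 0.9, so the threshold separates
the regimes with margin.

LD is the squared Pearson correlation of dosages (0/1/2, not phased
haplotypes), averaged within 5-kb window pairs across the region ± 1 Mbp,
for all individuals or within a homozygote class; monomorphic SNPs in the
subset are excluded. Allele sharing classifies SNPs by within-homozygote
group frequencies: shared in [10%, 90%] in both groups, diagnostic > 90%
in one and < 10% in the other, and an explicit third class "other" for
everything else (the named classes alone do not partition the range).
Gene flux is shared/(shared + diagnostic), overall and per 10-kb window.

## Trees

The pool distance is the mean absolute frequency difference over SNPs
with data in both pools. Neighbor joining follows Saitou–Nei with the
standard Q-criterion; ties are broken by taxon-name order (the smallest
leaf name in each subtree is its sort key), and a negative branch length
is clamped to zero with the deficit moved to its sibling edge so the pair
sum — and therefore path lengths — is preserved. The final three nodes
are joined by the three-point formulas into a trifurcating root, the
conventional unrooted representation. On additive matrices the tree
reproduces the input path lengths exactly (tested against brute-force
topology fitting and an independent NJ implementation).

## Genome–environment association

Environmental variables are standardised (mean 0, SD 1, ddof = 1;
zero-variance variables dropped) and pruned in two logged stages: while
any pair has |r| ≥ 0.7, the member of the worst pair with the larger mean
|r| to all other variables is dropped (ties by name order — the rule is a
package choice, recorded step by step so runs are auditable); then the
highest-VIF variable is dropped iteratively until all VIF < 5.

RDA centres the pools × SNPs frequency matrix, regresses it on the
predictors by least squares, and eigen-decomposes the fitted values.
Axis variance fractions are eigenvalue shares of the *total* variance;
constrained + residual sums of squares add to the total identically. With
a single predictor the constrained sum of squares equals the sum over
SNPs of per-SNP regression sums of squares (the brute-force oracle in the
tests). Rank-deficient predictor sets are fatal, naming the dependent
columns.

Significance uses pseudo-F = (SS_c/q)/(SS_r/(n−q−1)) with direct
permutation of predictor rows, p = (1 + #{F* ≥ F})/(nperm + 1) (default
nperm = 9999). Per-variable (marginal, type-III-like) tests permute the
component of one variable orthogonal to the others while holding the rest
fixed; with a single constraining matrix and no conditioning variables
this residual scheme and raw-row permutation coincide asymptotically.
Stepwise selection is bidirectional on these marginal permutation tests
with entry p < 0.05 and exit p > 0.1 (thresholds are package defaults,
exposed as arguments; 1000 permutations per test by default).

## Synthetic data

The generator emulates the *statistical* structure of a two-ecotype
pool-seq study, not its genealogy:

* 15 pools by default (3 spring, 10 fall, 1 summer, 1 mixed; fall pools
  split 7 north / 3 south), 41–50 diploids each, depth ~ Poisson(67) per
  SNP per pool — the observed median-depth range is 57–77×;
* background sites: ancestral p ~ Uniform(0.05, 0.95), pool frequencies
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.01 — an
  island-model stand-in chosen because no demographic model is specified;
* divergent loci: seasonal groups' ancestral frequencies differ by δ
  (non-seasonal pools sit at the midpoint), pools deviate with the
  background F;
* inversion block: pool haplotype-B frequency f = logistic(a + b·z) of
  the standardised winter-temperature variable (itself a latitudinal
  cline plus noise); diagnostic sites have haplotype-class frequencies
  < 5% vs > 95%, shared sites are drawn in 25–75% within both classes so
  that sampling noise rarely crosses the 10/90 classification thresholds;
  the shared:diagnostic site ratio is the gene-flux parameter;
* reads are sampled in two stages — allele count from the pool's 2N
  chromosomes, then reads from the realised pool frequency — so the
  n_eff correction has a real effect to detect;
* individual genotypes draw two haplotypes per individual from the
  pool's f, with unlinked flanking SNPs added for LD contrast.

Deliberately *not* emulated: linkage among background SNPs (sites are
independent, so LD-decay behaviour outside the inversion is not
testable), recombination maps, mutation-model detail, indels and the
upstream read-level artefacts (the filters are exercised on count-level
consequences only). Passing tests therefore demonstrate estimator
correctness and signal recovery under the assumed sampling model, not
robustness to alignment or calling artefacts in real data.

## Problem sizes and numerical choices

Simulated problem sizes in the tests and the acceptance script are scaled
to keep full runs fast while leaving comfortable statistical margins:
20,000 SNPs for FST recovery (estimator noise ≪ the target band),
3,000-SNP genomes with a 200-SNP planted locus for scan localisation
(100 replicates), 500 inversion sites for gene-flux recovery (binomial
SE ≈ 0.018 against a ±0.05 band), 1,000 null runs at 199 permutations for
RDA calibration (SE ≈ 0.007 against the [0.03, 0.07] band) and 100
replicates for power. All randomness flows from explicit seeds; fixing
the seed fixes every output byte. Degenerate inputs (zero depth, constant
matrices, empty groups, missing distances) either raise with a named
cause or propagate missingness — never silent zeros.
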