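# Methods

`longevar` implements the statistical core of a staged case–control
rare-variant study: a cohort of long-lived individuals ("cases",
e.g. centenarians) is compared with controls over targeted gene
regions, first variant-by-variant, then gene-by-gene with
variance-component kernel tests, followed by functional
prioritization, sub-pathway over-representation, and extraction of a
protein–protein interaction subnetwork around the top genes.

## Single-variant tests

Allelic association uses the two-sided Fisher exact test on the 2×2
allele-count table (rows = groups, columns = minor/major allele).
Two-sidedness follows the point-probability convention: the p-value is
the sum of hypergeometric probabilities, at the observed margins, of
all tables no more probable than the observed one. Genotypic tests use
the same conditional construction on the 2×3 genotype table, computed
by complete enumeration; this is exact but only feasible at desk-scale
margins, so an enumeration cap (default 2×10⁶ tables) guards it and
directs larger problems to the allelic test.

Published association tables usually print group allele frequencies to
three decimals rather than counts. `reconstruct_counts` bridges back to
integers by round-half-up of MAF × 2n; with 450 cases and 500 controls
this reproduces the printed p-values of the validated upstream promoter
variants (0.0022 and 0.0018) exactly at four decimals.

Allele frequencies are carried internally as *alternate*-allele
frequencies; minor-allele folding is applied only where a weighting
function expects a MAF. Missing genotypes are excluded per variant
(complete case). LD is reported as the squared Pearson correlation of
dosages over pairwise-complete individuals; a monomorphic variant
yields NaN rather than an arbitrary 0 or 1.

## Gene-based kernel tests

For a binary phenotype with no covariates the null model is an
intercept-only logistic fit: μ̂ equals the case fraction, residuals
y−μ̂, variance μ̂(1−μ̂). Covariates are deliberately out of scope: with
very rare variants a sex- or age-adjusted model adds parameters the
score test cannot support, and the study design this emulates used
none.

With per-variant score S_j = Σᵢ (yᵢ−μ̂) g_ij and weight
w_j = Beta(1,25) density at the folded sample MAF (whole-sample MAF, the
kernel-test convention), the SKAT statistic is Q = Σ_j w_j² S_j².
Under the null Q ~ Σ_k λ_k χ²₁ with λ the eigenvalues of the weighted,
null-variance-projected genotype cross-product
v·W½ Gᶜ′ Gᶜ W½ (Gᶜ column-centered). Eigenvalues below 1e-10·λ_max are
truncated for stability. The tail probability comes from
characteristic-function inversion (Imhof form, adaptive quadrature with
an oscillation-aware truncation point and the integrator's error
estimate as the acceptance gate); a single eigenvalue short-circuits to
the exact scaled-χ²₁ form. If inversion fails or returns a value
outside (0,1], a moment-matching fallback maps Q onto a scaled
noncentral chi-square agreeing in mean, variance and skewness; the
method actually used is recorded on every result.

The burden statistic is Q_b = (Σ_j w_j S_j)², a 1-df scaled chi-square.
SKAT-O scans Q_ρ = (1−ρ)Q_SKAT + ρQ_b over a ρ grid (default
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}) and combines the per-ρ
minimum p through the standard one-dimensional mixing integral over the
shared burden-direction chi-square; ρ=1 is evaluated exactly as the
burden test and capped at 0.999 only inside the integral where 1−ρ
divides. The combined p is clipped to [min_ρ p_ρ, |grid|·min_ρ p_ρ],
its theoretical envelope. SKAT-C splits variants at the rare/common MAF
threshold (0.05), weights the rare block by Beta(1,25) and the common
block by Beta(0.5,0.5), and tests the concatenated weighted kernel, so
a single-class input reduces exactly to SKAT with that class's weights.

### Pooled-frequency adaptation

Pooled sequencing observes per-pool allele frequencies, not genotypes.
The adaptation substitutes each pool's frequency for the allele counts
of the individuals it contains: member i of pool k enters with dosage
2×AF_k, the sample stays at the individual level, and weights use the
across-pool size-weighted MAF (identical to the substituted matrix's
sample MAF). Because pools are phenotype-homogeneous this preserves
every per-variant score exactly while removing the within-pool genotype
variance from the null eigenvalue spectrum. Two consequences, both
verified by the test suite:

* with unit pools and exact frequencies the test is bit-identical to
  individual-level SKAT;
* with real pools the p-value is systematically underestimated
  (anti-conservative), which every pooled result flags. The alternative
  construction — treating each pool as one observational unit — was
  evaluated and rejected: it is *less* powerful than individual-level
  SKAT (pooling then strictly loses information), which contradicts the
  documented behaviour of the frequency-substitution approach this
  module reproduces.

Read-sampling noise is modeled binomially at the pool's true frequency
with a configurable per-pool depth; infinite depth gives exact
frequencies. Pool topology (default pools of 50) is configurable since
real pooled designs vary and the emulated study did not publish its
pool layout.

## Prioritization rules

Genotyping candidates after the single-variant scan are the union of
(a) p < 0.05, (b) rare variants (pooled MAF < 0.05) with any group
frequency difference, and (c) predicted-functional coding variants
(nonsynonymous, stop-gain, stop-loss, frameshift, splice) with any
group difference. The minimum frequency difference for (b) and (c) is
configurable and defaults to "any nonzero difference" because no floor
is standard.

Functional strata for stratified gene tests: *coding* = the
protein-altering classes above; *regulatory* = RegulomeDB-style integer
class ≤ 5 **and** overlap with a TF-binding site or DHS, **or** a 3′UTR
variant with ≥ 1 Argonaute CLIP-seq experiment over it (a proxy for
microRNA targeting); *combined* = coding ∪ regulatory. The 3′UTR rule
is folded into the regulatory stratum rather than kept as a fourth
class. RegulomeDB ordering uses the leading integer only ("3a" ranks
as 3); letter subclasses are retained for display. Variants without an
annotation record classify as non-functional (conservative), with a
logged tally.

## Enrichment

Sub-pathway over-representation is the one-sided hypergeometric tail:
for a set of m genes with k significant, given K significant in the
N-gene universe, p = P(X ≥ k). One-sidedness matches the enrichment
framing of the question. Nominal p-values are primary — candidate-gene
studies of this design report them uncorrected — and a
Benjamini–Hochberg column is emitted as supplementary output.

## Subnetwork extraction

The background interactome is an undirected simple graph
(self-interactions dropped, duplicate edges merged). Given seed genes,
the subnetwork is the union of **all** shortest paths between every
seed pair whose distance is at most L*. The default cutoff is the
per-seed nearest-partner maximum: the smallest L at which every
reachable seed is an endpoint of some retained path — the minimal rule
that includes every seed. A global-max mode (largest finite pairwise
seed distance) is available behind a flag since the cutoff convention
differs between tools. Seeds disconnected from all others are excluded
with a warning rather than failing the run.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not
sequencing reads:

* two groups (default 450 cases / 500 controls) with genotypes drawn
  per group under Hardy–Weinberg at the group allele frequency —
  standard, and consistent with the allele-count tests;
* a rare-dominated MAF spectrum: a two-part uniform mixture with 81%
  of mass on (0.002, 0.05), matching the observed rare fraction in
  targeted capture of candidate gene regions;
* region classes drawn from the observed mix (intronic 50.96%,
  upstream 13.36%, exonic 10.38% split across coding-effect classes,
  remainder UTRs and splice sites);
* designated causal variants parameterized directly as
  (case MAF, control MAF) pairs — the form in which such studies report
  effects — with defaults of the magnitude of the validated promoter
  and intronic variants (e.g. 0.001→0.012, 0.023→0.050, 0.063→0.112);
* pooled sequencing at the allele-frequency level with binomial read
  noise;
* RegulomeDB-style annotation labels with ~40% of variants at integer
  class ≤ 5, TF/DHS overlap probability 0.6, Poisson(0.3) Ago counts —
  prevalences chosen so every prioritization branch is exercised.

One global seed drives three named substreams (genotypes, pooling,
annotations), so any stage can be regenerated independently and
identical config+seed is bit-reproducible.

What the generator does **not** model: linkage disequilibrium between
variants (each variant is drawn independently, so LD-based validation
uses duplicated columns), population structure and relatedness,
genotyping/calling error, departures from Hardy–Weinberg, and
covariate effects. Passing tests therefore demonstrate correctness of
the statistical machinery under the design's idealized assumptions,
not robustness to those real-data complications.

## Problem sizes and numerical conventions

The packaged experiments use desk-scale sizes chosen to keep full runs
comfortably reproducible on a single core: 2,000 null replicates
(n = 200, 20 variants) for type-I calibration, 200 replicates for the
pooled/individual comparison, 100 runs of 50 genes for recovery, 500
random tables and 200 random graphs for oracle sweeps. Determinism:
library code contains no hidden randomness; every simulation takes an
explicit seed, and the pipeline manifest records config, seed, and a
SHA-256 checksum of every output file.

## Known limitations

* The binary-trait score test without small-sample moment adjustment is
  mildly conservative at moderate n with very rare variants (measured
  empirical type-I ≈ 0.035 at α = 0.05, n = 200, 20 rare-heavy
  variants). Resampling/moment corrections exist in the literature but
  are deliberately out of scope here; at the emulated study's n ≈ 950
  the effect shrinks.
* The 2×3 exact genotypic test is enumeration-bound; use the allelic
  test at large margins.
* The pooled adaptation is anti-conservative by construction; treat
  pooled p-values as screening statistics, not calibrated error rates.
* No covariate adjustment, kinship correction, or multi-allelic joint
  modeling (multi-allelic sites are split into biallelic records).
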