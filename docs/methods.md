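# Methods

## The model

`owasjoint` tests genomic *segments* — 5 kb tiles of the ±100 kb
regulatory windows around gene TSSs — for association with a complex
trait, weighting each SNP's GWAS evidence by its predicted effect on
chromatin accessibility ("openness") in each of L cell types, and then
aggregating across cell types.

**Per cell type.** Let Ω_s be the SNPs of segment s, w_j the predicted
openness effect of SNP j in the given cell type, z_j its GWAS z-score,
and σ̂_j the SD of its dosage in an LD reference panel. The per-individual
openness score of the segment is O_s = X_s W_s; the summary-statistics
z-score for regressing the phenotype on O_s is

    Z_s = Σ_{j∈Ω_s} w_j σ̂_j z_j / σ̂_s,      σ̂_s² = W_sᵀ Ĉov(X_s) W_s,

with Ĉov(X_s) estimated from the panel. p_{l,s} = 2·Φ(−|Z_s|). The
approximation holds because each marginal z_j estimates the covariance of
the phenotype with SNP j up to a common scale, so the weighted sum
estimates Cov(y, O_s) and σ̂_s supplies the matching normalization; the
equivalence with the individual-level t-statistic is exercised directly
by the oracle-equivalence acceptance test (r > 0.99 over 500 simulated
segments when the cohort is its own panel and shrinkage is off).

**Across cell types.** The L per-cell-type p-values are combined with the
Cauchy combination (ACAT):

    T_s = Σ_l η_l · tan((0.5 − p_{l,s})·π),      p_s = 1/2 − arctan(T_s)/π,

with non-negative weights η_l summing to 1 (uniform by default: no prior
knowledge of the trait-relevant cell types). Because a weighted sum of
standard Cauchy variables is again standard Cauchy in the tail regardless
of dependence, the transform is calibrated under the null for arbitrarily
correlated cell types — the property that makes the aggregation cheap
(no permutations, no covariance of tests needed). η = e_k recovers the
single-cell-type test exactly. Segment significance uses Bonferroni:
p_s < α / (number of testable segments), α = 0.05. A gene is reported
significant when any segment overlapping its own ±100 kb window is; its
gene-level p is the minimum segment p (a reporting convention, not a
calibrated gene test).

## LD processing

With a small panel the raw per-segment covariance is rank deficient and
σ̂_s² can collapse toward 0, inflating Z_s. Two guards:

1. **Perfect-LD pruning** (r² ≥ 0.99): greedy, visiting SNPs by
   decreasing priority (GWAS evidence; |z| is used, which orders exactly
   as −log10 p) with ties broken toward the smaller position, keeping a
   SNP iff its r² with all kept SNPs is below threshold. This is
   deliberately a deterministic pruning rather than a reimplementation of
   PLINK's clump machinery — the only goal is removing perfect LD.
   Pruned SNPs are excluded from the Z_s sums: the pruned set *is* the
   test's SNP set.
2. **Schäfer–Strimmer shrinkage** toward the identity correlation:
   r*_ij = (1 − λ*) r_ij (i ≠ j) with the analytic intensity
   λ* = clamp(Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r²_ij, 0, 1), where Var̂(r_ij)
   is the empirical variance of the standardized cross-products
   (Var̂(r_ij) = n/(n−1)³ · Σ_k (x_ki x_kj − w̄_ij)²). The covariance is
   reassembled as cov_ij = r*_ij σ̂_i σ̂_j, so the diagonal keeps the
   unshrunk sample variances. With λ* > 0 the matrix is strictly positive
   definite (min eigenvalue ≥ λ* · min σ̂²); a floor of 1e-12 on the
   applied intensity covers the measure-zero λ* = 0 case. Note that under
   *independent* columns the analytic ratio converges to 1 (full
   shrinkage), which is the estimator's correct answer, not a defect;
   λ* → 0 as n grows only when real correlation is present.

σ̂_j is taken from the reference panel (the only genotype source in the
summary-statistics setting). Panel dosages are mean-imputed per variant
before any moment is computed; monomorphic panel variants are excluded
during harmonization.

## Numerical choices

- **Cauchy transform**: tan((0.5 − p)π) is evaluated as 1/tan(pπ)
  (cotangent identity; −1/tan((1−p)π) for p > 0.5), which keeps full
  relative precision for small p where the naive form loses ~|log p|
  digits near the pole; below p = 1e-15 the asymptote 1/(pπ) is used, and
  the two branches agree to < 1e-6 relative at the switch. The
  back-transform is written atan2(1, T)/π (≡ 1/2 − arctan(T)/π), again
  exact in the tail; for T > 1e15 this is numerically the reciprocal form
  1/(Tπ). Combined p-values are clamped to the open interval (0, 1).
- **p-value floor**: 2Φ(−|z|) is floored at the smallest positive double
  (≈ 4.9e-324) so extreme z never yields exactly 0.
- **Untestable segments**: if σ̂_s² < 1e-12 · max_j (w_j σ̂_j)² (e.g.
  all-zero weights), the segment's p is reported missing, excluded from
  the Bonferroni denominator, and its η renormalized away in the joint
  combination — not reported as p = 1.
- **Ties at the threshold**: strict inequality (p = threshold is not
  significant).
- **Harmonization sign convention**: the panel's counted allele is the
  master coding; both z and every w flip sign when keyed to the opposite
  allele; strand-ambiguous (A/T, C/G) variants are dropped; allele
  mismatches are dropped rather than force-matched.

## The synthetic cohort generator

The simulation study needs individual-level genotypes; the generator
emulates a GWAS cohort of n = 15,757 at segment scale:

- **Genotypes**: per individual, two haplotypes from a latent AR(1)
  Gaussian copula (lag-one correlation `ld_rho`, default 0.5) thresholded
  at each SNP's MAF quantile, MAF ~ U[0.05, 0.5]; dosage = haplotype sum.
  This produces blocks with realistic local r² decay but not real LD maps
  (no hotspots, no long-range structure, no allele-frequency spectrum
  below 0.05).
- **Segments**: 2–20 SNPs each (segments with < 2 SNPs are removed from
  the simulation design), 500 segments, 10 replicates.
- **Openness weights**: dense (sparsity 1.0 — deltaSVM-style predictors
  score every SNP), drawn per SNP from an L-variate normal with unit
  variance and cross-cell-type correlation 0.5 (real predicted openness
  effects are correlated across cell types; the value is a first-class
  knob).
- **Phenotype**: y = Σ_l λ_l O_l + ε with ε i.i.d. normal; the noise SD
  is solved so the segment explains the target heritability h²
  (0.02% low / 0.1% high) *exactly in-sample*. The three causal
  architectures are λ = (1,0,0), (½,½,0), (⅓,⅓,⅓); the null is λ = 0
  with y ~ N(0,1).
- **Evaluation**: marginal GWAS on the simulated cohort, the cohort
  itself as LD panel (pruning + analytic shrinkage active, so the full
  pipeline is exercised), rejection threshold 0.05/500 per test; methods
  compared are the three single-cell-type tests, their union with
  Bonferroni (each p against threshold/3), and the joint test.

What passing these simulations does *not* show: behavior under real LD
(reference-panel mismatch), real deltaSVM weight distributions
(heavy-tailed, locally clustered), case-control traits, or rare variants.

## Problem sizes in the test suite

The power-ordering and printed-improvement checks run the full design
(n = 15,757, 500 segments × 10 replicates, six scenarios). The null
calibration runs at n = 4,000 — under the null the per-test calibration
is independent of cohort size, and this keeps the suite fast. The
oracle-equivalence check uses n = 5,000 × 500 segments, ample for the
o(1) equivalence to express itself.

## Known limitations

- The gene-level call (min-p over segments, no second multiplicity
  layer) mirrors the segment-level Bonferroni convention; it is a
  labeling of segments by gene, not a calibrated gene-level test.
- Overlapping gene windows are merged before tiling so each SNP is
  tested once genome-wide (a single Bonferroni denominator); per-gene
  re-testing of shared SNPs is deliberately not offered.
- The replication-rate analysis bins discovery SNPs at fixed p cut
  points ((0, 5e-6], … , [5e-3, 0.05)) and uses a one-sided exact
  binomial test of the prioritized group against the non-prioritized
  replication rate *per bin*; pooling across bins is not implemented.
- η is user-supplied or uniform; data-driven weight learning is out of
  scope.
- No liftover, no VCF dosages, no imputation of missing GWAS variants.
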