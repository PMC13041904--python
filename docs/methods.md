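# Methods

This note documents the statistical models implemented in `scqtl`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not emulate.

## Synthetic cohorts (`scqtl.simdata`)

Genotypes: each variant's minor-allele frequency is drawn uniformly from
`maf_range` (default (0.05, 0.5]). Within LD blocks of `ld_block_size`
variants (default 10), each haplotype is a latent equicorrelated Gaussian
vector (correlation `ld_rho`) thresholded at the allele-frequency quantile;
the genotype is the sum of two independent haplotypes. This yields exact
Hardy–Weinberg proportions per variant and a tunable within-block r²
(approximately `ld_rho` for common variants, decaying for rare ones). The
exact LD pattern of real cohorts (distance decay, recombination hotspots)
is *not* modelled; downstream analyses only require the presence/absence
of block correlation. Variants sit on one synthetic chromosome at fixed
spacing (default 50 kb), and optional Gaussian dosage noise (clipped to
[0, 2]) emulates imputation uncertainty.

Counts: cell numbers per donor × cell type are negative binomial
(default mean 30, dispersion 3, mimicking highly variable per-donor cell
recovery). For gene g in cell c of donor d,

    y ~ NB(mu, theta),   log mu = base_g + beta[g, ct] * dosage
                                + slope[g, ct] * cq(c) * dosage
                                + a[g, d] + log s_c

with gene baselines `base_g ~ N(log 0.5, 0.5²)` (≈ 0.5 UMI per cell per
gene), donor random intercepts `a[g, d] ~ N(0, donor_sd²)` (default sd 0.3,
a moderate donor effect), per-cell lognormal size factors (sd 0.4), NB
dispersion `theta = 2` (variance ≈ mu + mu²/2, typical for UMI pseudo-bulk
at this depth), and `cq` the centered pseudotime quantile (1..6). The
effect grid cycles over genes; default log-scale effect 1.0 for
global/category/specific patterns and interaction slope 0.15 per quantile
for dynamic genes — values chosen for test power, since realistic
effect-size distributions for this design are not established. Pseudotime
lives on [0, 30] (uniform or bimodal) and is defined only for the
trajectory branch (AT2 → Alveolar Transitional → AT1 in the default
palette); a configurable fraction of trajectory cells can receive infinite
pseudotime to exercise the removal rule. `n_umi` is recorded as the true
column sum of the simulated counts, so library-size offsets are exact.

What passing tests on these cohorts do *not* show: robustness to ambient
RNA, doublets, batch effects, cell-type misannotation, or non-NB
zero-inflation — none of which the generator produces.

## Pseudo-bulking and normalization

Cell types qualify with ≥ 40 donors each contributing ≥ 5 cells; genes with
nonzero counts in ≥ 10% of all cells (both thresholds inclusive).
Qualifying counts are sum-aggregated per donor. Normalization is two-step:
per-donor counts-per-10k with log1p, then a per-gene rank-based
inverse-normal transform across donors with offset (r − 0.5)/n and average
ranks for ties. The second step is deliberately the *per-gene
inverse-normal* reading of "quantile normalization": it makes the linear
model's null exactly Gaussian and is the standard phenotype transform in
eQTL practice; across-sample distribution matching would be the other
defensible reading. Latent expression factors are plain expression PCs
(computed per cell type on the normalized matrix) rather than PEER
factors; the count is optimized the same way — the smallest count whose
eGene discovery is within 2% of the grid maximum.

## cis-eQTL mapping

Nominal associations use OLS via Frisch–Waugh: phenotype and dosages are
residualized against the covariates (plus intercept) once; the per-variant
slope, SE and t-test then equal the full-design OLS exactly with
df = n − (k + 2). Variant filters: MAF > 0.05, imputation R² > 0.3, cis
window ±1 Mb of the TSS, boundary inclusive. Monomorphic-in-sample
variants are skipped and logged. Top-variant ties break by larger |t|,
then smaller variant id.

The permutation scheme residualizes once and permutes residuals (the
fast, FastQTL-family behavior; a full re-fit mode exists behind
`mode="refit"`). Permuted residuals are re-projected onto the
covariate-orthogonal subspace before correlating with the dosage
residuals: without this, permuted vectors carry n − 1 effective degrees
of freedom while the observed statistic carries n − k − 1, and the
gene-level p-value's mid-tail inflates by roughly (k + 1)/n (measured as
~15–20% at 4 covariates and 120 donors). Per permutation the minimum cis p is recorded;
Beta(a, b) is fitted to the minima by Newton ML from a moment start, and
the adjusted p is the Beta CDF at the nominal top p. The
degrees-of-freedom recalibration some implementations apply ("true df") is
not implemented; on the synthetic cohorts the beta-approximated p tracks
the 10,000-permutation empirical p within ±0.01 without it. Storey
q-values use a single λ = 0.5 (robust at the few-hundred-to-few-thousand
gene scale here; the smoothing-spline estimator is unnecessary); below 20
genes the estimator falls back to π₀ = 1 (BH).

The NB mapper fits, per (gene, variant), a negative-binomial regression
(log link) of raw pseudobulk counts on dosage and covariates with a
log-library offset, dispersion by ML; non-converged fits fall back to
Poisson and are flagged.

## Cross-cell-type effect sharing ("mash-lite")

Prior on the true effect vector across R cell types: point mass at zero
plus zero-mean multivariate normals with covariances from canonical
patterns (identity, R singletons, equal-effects) and data-driven patterns
(empirical covariance of strong-set z-scores and its top 2 principal
components, eigenvalue-clipped to PSD), each scaled over a geometric grid
from 0.1·min(se) to 2·max|beta| of length 20. Unlike the full mash
machinery there is no extreme-deconvolution refinement of the data-driven
matrices and no common-baseline/contrast handling — the posterior
machinery is otherwise the same. Only mixture weights are free; they are
estimated on a random subset of tested pairs by EM with SQUAREM
acceleration and a monotonicity safeguard (the penalized marginal
likelihood is asserted non-decreasing). A mild Dirichlet prior (10
pseudo-counts on the null) resolves the likelihood ridge between the point
mass and sub-resolution scale components in favour of the null, as in
mashr's null-biased default. The residual error correlation is the
z-score correlation of near-null rows (max |z| < 2). Missing
(gene, variant, cell type) entries are handled by setting bhat = 0 with a
very large SE, which marginalizes the Gaussian likelihood over the
unobserved coordinate.

lfsr = min{P(b ≤ 0 | data), P(b ≥ 0 | data)}, point mass counted on both
sides; significance lfsr < 0.05. Sharing classes partition rows with any
significant cell type: specific (1 cell type), category-shared (≥ 2, one
of endothelial/epithelial/immune/stromal), cross-category-shared (≥ 2
categories). Pairwise sharing conditions on significance in *both* cell
types and requires same sign and fold ratio within [0.5, 2] (inclusive; a
zero posterior mean fails the rule).

## Annotation

LD pruning mirrors `--indep-pairwise 250 50 0.9`: sliding 250-variant
windows advancing by 50; within a window each pair with r² > 0.9 loses its
lower-MAF member (ties: the later position) — plink's exact tie-breaking
is not public, so membership may differ slightly; downstream statistics do
not depend on it materially. Enrichment per annotation label is a
two-sided Fisher exact test of pruned eQTL vs pruned non-eQTL SNPs, BH
corrected. Zero cells report the unconditional odds ratio (0 or ∞) rather
than a Haldane correction. Interval queries are 0-based half-open (a
1-based SNP position p is inside [start, end) iff start ≤ p−1 < end). The
TSS-distance comparison uses a one-sided Mann–Whitney U (shared closer
than specific); the underlying study shows only densities, so the test
choice is ours. ATAC-peak assignment precedence is cell-type-specific >
multi-category > other; non-overlapping SNPs are excluded from the 2×3
chi-square.

## Dynamic eQTLs

Finite-pseudotime trajectory cells are ranked into Q = 6 equal-count bins
(±1 cell; infinite pseudotime removed; rank-based, hence invariant to
monotone transforms). The interaction model per (gene, variant) is

    y_cell ~ NB(mu, theta),
    log mu = b0 + b_g·dosage + b_t·q + b_int·(dosage × q)
           + covariates + log(nUMI),    u_donor ~ N(0, sigma²),

with q the centered quantile treated as continuous, covariates
percent-mito, expression PCs (default 6, computed once on the trajectory
cells — not per quantile), genotype PCs and age. The 1-D random intercept
is integrated by adaptive Gauss–Hermite quadrature (9 nodes; Laplace = 1
node as fast mode; donor fixed-effects NB regression retained as a test
oracle). Optimization is BFGS on (beta, log theta, log sigma) with
gradients and the Wald covariance from central finite differences
evaluated in one batched pass (all perturbed parameter vectors share the
vectorized inner Newton/quadrature sweep); centering the quantile
decorrelates main and interaction terms without changing b_int. The Wald
test on b_int, BH-corrected across tested pairs, defines dynamic eQTLs.
Per-quantile effects refit the model within each bin (donor random effect
retained; bins under 50 cells or without dosage variation are missing),
and a 1/se² weighted regression of the per-quantile effects on quantile
classifies the trend: linear / quadratic / both / none at p < 0.05 on the
highest-order term, requiring ≥ 4 informative bins. Regulon-activity
trends use the same linear/quadratic regressions at the cell level.

## Colocalization and TWAS

Per variant and trait, the Wakefield log-ABF is
½·log(V/(V+W)) + z²W/(2(V+W)) with V = se². Prior effect variance W:
(0.15·sdY)² for quantitative traits (sdY estimated, when sample size and
MAF are available, from the regression identity
var(beta) ≈ sdY²/(2·n·maf(1−maf)); otherwise sdY = 1) and 0.2² on the
log-odds scale for case-control. Hypothesis sums accumulate by
log-sum-exp with priors p1 = p2 = 1e-4, p12 = 1e-5; loci are ±100 kb
windows (inclusive) around GWAS top SNPs that contain at least one eQTL
variant; PP.H4 ≥ 0.7 flags colocalization. With p12 = 0, PP.H4 is exactly
0; H4 is invariant to trait order.

TWAS weights are trained on covariate-residualized pseudobulk expression
with standardized cis dosages: four families (top-SNP; ridge as the BLUP
surrogate, penalty by internal grid; lasso; elastic net with l1_ratio 0.5)
scored by k-fold (default 5) cross-validated R², best family wins. The
cis-heritability filter is a permutation test on the winning family's CV
R² (default 100 permutations) — a deliberate substitute for GREML-style
REML, which is unstable at ~120 donors; its role (excluding genes whose
expression is not cis-predictable) is preserved, together with the CV
correlation-test filter (both p < 0.05). The association statistic is
z = w'z_gwas / sqrt(w'Rw) with R the in-sample dosage correlation matrix
regularized as (1−ε)R + εI, ε = 0.01; BH FDR within cell type.

## Numerical conventions and degenerate inputs

Dosages count alternative alleles (0–2, fractional allowed); flipping
ref/alt flips effect signs exactly. Beta-fit refuses fewer than 100
permutations. NB GLMM linear predictors are clipped at ±30 on the log
scale; non-converged or singular fits are flagged, never silently
dropped. Chi-square tests drop all-zero columns with a warning; expected
cell counts < 1 warn. Zero-library donors are excluded from
normalization with a warning.

## Problem sizes used in tests and the acceptance script

Simulated cohorts use 80–120 donors, 30–500 genes, 1–3 cell types,
~5–25 cells per donor per type, and 40–150 variants — sizes chosen so the
full chain (including 8,000+ mixed-model fits in the interaction
calibration study and 10,000-permutation comparisons) runs comfortably on
one CPU while keeping every statistical check at its stated replication
level. The acceptance script runs reduced versions of the same studies
(e.g. 200 null interaction genes instead of 20 × 400) and reports the
measured quantities; all randomness derives from the single `--seed`.

## Known limitations

- With very small gene panels (tens of genes), expression PCs can absorb
  individual strong cis effects, erasing the very signal being mapped;
  the factor-count optimization (or `n_factors=0`) is the remedy. Real
  panels of thousands of genes dilute any single gene's contribution.

- The latent-Gaussian LD model has no distance decay; enrichment and
  pruning behavior on real LD maps is untested.
- The EB model fixes data-driven covariances at their initial estimates
  (no extreme deconvolution); with few strong rows the PCA patterns are
  noisy, mitigated by the scale grid and the null-biased prior.
- The NB GLMM Wald test relies on a finite-difference Hessian; for genes
  with near-boundary dispersion or variance parameters the SE can be
  unstable (flagged through the convergence field).
- TWAS "BLUP" is ridge with CV-chosen penalty, not an exact mixed-model
  BLUP; heritability filtering is CV-permutation-based, not REML.
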