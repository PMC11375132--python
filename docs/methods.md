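# Methods

## Model and estimands

Two-sample MR works from per-variant marginal GWAS associations: exposure
effects (β̂_Xj, σ̂_Xj) from one cohort, outcome effects (β̂_Yj, σ̂_Yj) from a
disjoint cohort. Under the linear structural model the marginal effects
satisfy β_Yj = θ β_Xj + α_j with θ the causal effect of exposure on outcome
and α_j the instrument's horizontal-pleiotropy effect.

The conditional framework decomposes α_j = α*_j + ρ′_j r_j: a *biological*
part α*_j intrinsic to the instrument, and an *LD-induced* part transmitted
from neighboring variants G_j with direct (or confounder- or
exposure-mediated) outcome effects r_j via the LD correlations ρ_j. On the
conditional-effect scale — effects of Z_j given G_j — the same relation
holds with α*_j alone: β*_Yj = θ β*_Xj + α*_j, and θ is unchanged. Stage 1
estimates the conditional effects; stage 2 applies robust estimators whose
assumptions (balanced pleiotropy, majority/plurality validity) then only
need to hold for the biological part.

## Stage 1: conditional effects from summary statistics

All conditional algebra runs on the standardized scale (unit-variance
genotypes and trait), where the marginal coefficient of SNP j is the
genotype–trait correlation, recovered exactly from the reported summary
statistics as `b_j = z_j / sqrt(z_j² + n_j − 2)` with `z_j = β̂_j/σ̂_j`
(the t-statistic of a simple regression with intercept). For a SNP set S
with panel LD matrix R:

* joint coefficients `b_joint = R⁻¹ b_marg`;
* residual variance `σ̂² = max(1 − b_margᵀ R⁻¹ b_marg, 10⁻⁶)` (the floor
  keeps standard errors finite under near-perfect fits);
* `se(b_joint) = sqrt(σ̂² · diag(R⁻¹) / n_eff)` with `n_eff` the median
  per-SNP sample size of the fitted set (robust to outlying N);
* two-sided normal p-values.

When the reference panel *is* the GWAS sample, these joint estimates equal
individual-level multiple-OLS coefficients and standard errors (with
residual variance normalized by n) to machine precision — the test suite
pins this identity at 10⁻⁶. With an external panel they are the usual
summary-statistic approximation. Results returned to the user are mapped
back to each SNP's input scale through the per-SNP factor `β̂_j / b_j`
(≈ sd(trait)/sd(genotype)), so an empty conditioning set reproduces the
input marginals bit for bit.

**Selection.** Per LD block, a forward–backward stepwise search on the
outcome statistics: seed with the block's smallest-p SNP if p ≤ p_cojo
(default 5×10⁻⁶); repeatedly add the candidate with the smallest
conditional p-value subject to p ≤ p_cojo and max |r| < 0.9 with the
current set; after every addition drop any member whose joint p exceeds
p_cojo; stop when no candidate qualifies. The model size is capped at
min(block size, n_eff/10). Candidate order is canonicalized by genomic
position then identifier, making the output independent of input ordering;
p-value ties break the same way.

**Conditioning.** Instruments with |r| ≥ 0.9 to any selected SNP are
excluded (their conditional effects are not identifiable in practice);
the rest take their coefficients from one joint fit of
(instruments ∪ selected set) per trait. A block whose LD matrix is
numerically singular (condition number ≥ 10⁸) falls back to marginal
estimates with a logged flag rather than aborting the run.

## Stage 2: estimators

* **IVW** (multiplicative random effects): θ̂ = Σ(β_x β_y/σ_y²)/Σ(β_x²/σ_y²);
  the fixed-effect se is inflated by sqrt(max(1, Q/(m−1))) — under-dispersion
  is not allowed.
* **RAPS**: adjusted profile score under β̂_x ~ N(γ, σ_x²),
  β̂_y ~ N(θγ + α, σ_y²), α ~ N(0, τ²). Standardized residuals
  t_j = (β̂_y − θβ̂_x)/√(σ_y² + θ²σ_x² + τ²); the θ- and τ²-score equations
  are solved by alternating bracketed scalar root-finds (Brent), which is
  robust to the boundary τ² = 0; sandwich standard error. Default loss is
  squared error with overdispersion; Huber (k = 1.345) optional, with the
  τ²-equation corrected by E[ψ(Z)Z].
* **Weighted median**: ratio estimates ordered ascending with weights
  ∝ β_x²/σ_y², linear interpolation of the cumulative-weight midpoints at
  0.5; seeded parametric bootstrap se (default 1,000 draws).
* **Weighted mode**: ratio estimates weighted by inverse delta-method
  variances; estimate is the argmax of a weighted Gaussian KDE with
  bandwidth φ × 0.9 × (weighted MAD × 1.4826) × m^(−1/5) (φ = 1 by
  default; weighted SD fallback when the MAD degenerates); seeded
  parametric bootstrap se. Zero-weight instruments are dropped, so they
  cannot perturb the bandwidth or grid.
* **cML** with BIC model averaging: for each candidate number K of invalid
  instruments, coordinate descent with closed-form updates (valid γ_j pools
  both traits; the invalid set is the K largest squared standardized outcome
  residuals), from the IVW start plus 10 seeded random starts;
  BIC(K) = 2·minL + K·log(n); model-average weights ∝ exp(−ΔBIC/2); the
  variance combines within-model profile-curvature variance and
  between-model dispersion. Ks that never converge are excluded with a
  warning (common at K near m−2, where the invalid-set assignment can
  cycle).
* **Cochran's Q** on ratio estimates with first-order weights, and
  **Steiger filtering** (remove an instrument iff its outcome
  explained-variance proxy z²/(z²+n) exceeds the exposure one; ties are
  retained).

Both frameworks run on the identical instrument list, so their outputs are
directly comparable; with selection disabled (p_cojo = 0) they coincide
exactly, which the suite asserts bit-for-bit.

Median/mode estimators sort instruments into a canonical order internally
before the seeded bootstrap, so results are invariant to the caller's input
order at fixed seed.

## Instrument selection and harmonization

Clumping is greedy by ascending p (ties: position, then id): a SNP is kept
iff its r² with every retained SNP within the window (default 10,000 kb,
inclusive, never spanning chromosomes) is below the threshold (default
0.001) at p ≤ 5×10⁻⁸. Harmonization intersects exposure, outcome and panel
SNPs, resolves swapped and strand-complemented alleles (flipping outcome
betas and frequencies), and drops palindromic A/T / C/G SNPs when the
exposure allele frequency falls in [0.42, 0.58] (policy `drop_ambiguous`;
`drop_all` available). Positions are 1-based; LDetect-style 0-based
half-open block files are converted on read.

## Colocalization sensitivity analysis

Per instrument, the ±200 kb region is scored under the single-causal-variant
model: per-SNP Wakefield log-ABFs (prior effect SD 0.15 for quantitative
traits, 0.2 for case-control) are combined in the log domain into the five
hypothesis likelihoods with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. High PP3
(≥ 0.75) or high PP4 with low per-SNP PP4-IV (< 0.5) both indicate
LD-induced pleiotropy at that instrument; PP4 ≥ 0.75 with PP4-IV ≥ 0.5
indicates the instrument itself is the shared causal variant. The 0.75
threshold on PP3 is a package choice (configurable); the PP4 and PP4-IV
thresholds are standard.

## Synthetic-data generator

Real genotypes are emulated by a Gaussian-copula haplotype model: per block,
MAFs ~ U(0.05, 0.5) and target adjacent allele correlations ~ U(0.3, 0.9);
a latent first-order Markov Gaussian chain is thresholded at the MAF
quantile per haplotype and the two haplotypes are summed. The latent
adjacent correlations are calibrated by bisection of the bivariate-normal
orthant probability so the *realized allele* correlations hit their targets;
targets above the Fréchet bound for a pair's frequencies are clamped to the
attainable maximum. Blocks are mutually independent and spaced 20 Mb apart
so the clump window never spans blocks.

Phenotypes follow the structural equations with confounder
U = ΣG_jφ_j + e_U, X = Σβ*_j Z_j + ΣG_jγ_j + U + e_X,
Y = θX + Σα*_j Z_j + ΣG_j r_j + U + e_Y, unit-normal noises, and **raw
additive genotype coding** — with β* ~ U(0.1, 0.2) over 20 blocks this puts
the exposure heritability from instruments near 0.07 and mean selected-
instrument F well above 100, matching the strong-instrument design, while
β* ~ U(0.02, 0.08) over 50 blocks gives the weak-instrument design with
median selected F near 48. Scenario placements of the neighbor effects:
(1) two neighbors with direct outcome effects r ~ U(0.1, 0.2) in a
configurable fraction of blocks, plus optional biological pleiotropy
α* ~ U(−0.1, 0) on a fraction of instruments; (2) one neighbor affecting
the confounder, φ ~ U(0.05, 0.15); (3) one neighbor affecting exposure
(γ ~ U(0.05, 0.15)) and outcome (r ~ U(0.1, 0.2)) in the first half of the
blocks; (4) as (1) with the weak-instrument effect range over 50 blocks,
LD-pleiotropy in 60% of blocks. Neighbors are drawn among block SNPs with
theoretical |r| to the instrument in [0.3, 0.7] (closest-to-0.5 fallback),
so LD-induced pleiotropy is material.

Each replicate draws two disjoint samples (default 50,000 each) for the
exposure and outcome GWAS; per-SNP simple linear regression (intercept
included) emits the summary statistics; the exposure sample doubles as the
LD panel (in-sample LD), switchable to an independent sample. The harness
pools type-I error / power at α = 0.05, bias, MSE and first-stage F
(β̂_x/σ̂_x)² before and after conditioning, all driven by one seed through
spawned per-replicate generators.

**What the generator does not emulate:** real LD is not Markovian and block
boundaries are not clean; allele-frequency spectra are not uniform;
genotypes here are Hardy–Weinberg-exact and missingness-free; sample overlap
and population structure are absent. Passing tests therefore demonstrate the
method's behavior under its stated model, not robustness to those
real-data complications. The validation runs use 30-SNP blocks (real LD
blocks span tens to hundreds of SNPs); instrument-strength summaries depend
on per-SNP effects and sample size, not block size, so this choice mainly
limits the number of candidate neighbors per block.

## Numerical choices and limitations

* LD matrices are mean-imputed, clipped to [−1, 1]; joint fits refuse
  condition numbers ≥ 10⁸ and name the worst pair.
* GWAS p-values use the t reference (n − 2 df); validation checks p/β/se
  consistency against the normal reference at 10% relative tolerance and
  only warns, since released summary files mix conventions.
* Per-SNP N is optional in input files; a dataset-level N can be supplied.
* The KDE argmax for the mode uses a 4,096-point grid over the ratio range
  ±3 bandwidths; its resolution is well below the bootstrap noise.
* A known regime where conditioning under-delivers: when outcome-associated
  neighbors sit near the selection threshold (|z| ≈ 4.6 at p = 5×10⁻⁶),
  stage 1 misses a fraction of them and the corresponding LD-induced
  pleiotropy survives into stage 2. At the study's full sample size
  (n = 50,000) neighbor effects r ≥ 0.1 are essentially always detected and
  the conditional framework is calibrated; at substantially smaller n the
  missed-neighbor fraction grows and directional residual bias reappears in
  *all* estimators. Relaxing p_cojo (e.g. 5×10⁻⁴) adjusts more instruments
  at the cost of conditioning on more noise; it is exposed in the config.
* Out of scope: multivariable MR, Egger regression, correlated-instrument
  estimators, overlapping-sample corrections, genome-build liftover,
  multi-allelic variants, and computing LD blocks (partitions are consumed,
  not estimated).
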