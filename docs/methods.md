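# Methods

## Structural model and simulator

The simulator generates individual-level data under a linear structural
model with *J* mutually independent biallelic SNPs (dosages
G_ij ~ Binomial(2, maf), maf = 0.3 by default), an unmeasured confounder
U, an exposure X and an outcome Y:

    U_i = Σ_j φ_j G_ij + ε_U
    X_i = Σ_j α_j G_ij + b U_i + ε_X
    Y_i = Σ_j γ_j G_ij + θ X_i + c U_i + ε_Y,

with independent standard-normal noise. The confounder coefficients
default to b = c = 1 (the structural equations carry unit coefficients on
U); both remain configurable. θ is the causal effect of interest, 0 or
0.2 in the study grid.

Instrument strengths α_j are drawn from Uniform(0, a), all non-negative.
The scale *a* is calibrated in closed form so the direct genetic effects
explain a target fraction R² (default 10%) of Var(X): with
Var(G_j) = 2·maf·(1−maf) and E[Σα_j²] = J a²/3,

    a = sqrt( 3 R² (b²+1) / ((1−R²) · J · 2 maf (1−maf)) ),

giving a ≈ 0.178 at J = 50 and a ≈ 0.126 at J = 100. The closed form
assumes φ = 0 (its derivation fixes Var(U) = 1); in the pleiotropy
scenario with φ ≠ 0 the realized R² is marginally below target, which is
immaterial to the comparisons the grid makes.

Four pleiotropy scenarios govern the invalid subset of SNPs (a uniformly
random subset of round(invalid_fraction·J) SNPs, redrawn each replicate):

1. none — all instruments valid (γ = φ = 0);
2. balanced, InSIDE satisfied — γ_j ~ N(0, 0.15), φ = 0;
3. directional, InSIDE satisfied — γ_j ~ N(0.1, 0.15), φ = 0;
4. directional, InSIDE violated — γ_j ~ N(0.1, 0.15), φ_j ~ U(0, 0.1).

The 0.15 is read as the standard deviation of the normal distribution.
Both populations of a replicate share one draw of (α, γ, φ) — the two
GWAS samples target the same underlying population — and differ only in
genotypes and noise.

## Selection layer

Inclusion is Bernoulli with logit(π_i) = e0 + e_x X_i + e_y Y_i +
e_g Σ_j G_ij. A mechanism (X, Y, G, X+Y, G+X, G+Y, G+X+Y, none) sets
which coefficients equal the shared selection effect e (grid: ±2, ±1,
±0.5, 0); e_g is a single scalar shared by all SNPs. The intercept e0 is
not a free parameter of the study: it is calibrated per (cohort,
mechanism, effect) by monotone root-finding so that mean π equals
oversample_factor × n_target / N (oversample 1.5 by default), after which
exactly n_target individuals are drawn uniformly from the Bernoulli
selectees. Calibration keeps the selected fraction comparable across
mechanisms — otherwise selection strength would be confounded with
sample size. If a Bernoulli draw falls short of n_target the oversample
factor doubles and calibration repeats (three attempts).

## GWAS summary statistics

Marginal one-SNP-at-a-time linear regressions (standard GWAS practice;
no covariate adjustment), classical normal-theory SEs with n−2 residual
degrees of freedom. Sample I contributes the exposure associations,
sample II the outcome associations; the samples never share individuals.
The harmonized table (columns `snp, beta_exposure, se_exposure,
beta_outcome, se_outcome`) round-trips through CSV/TSV.

## The eight estimators

All consume the summary table; shared conventions: first-order ratio SEs
(σ̂_Yj/|β̂_Xj|), inverse-variance weights β̂_Xj²/σ̂_Yj², two-sided
p-values (normal reference unless stated).

- **IVW** — weighted least squares of β̂_Y on β̂_X through the origin,
  weights σ̂_Y⁻²; multiplicative random-effects SE with the residual
  scale floored at 1 (never more precise than the fixed-effect fit).
- **MR-Egger** — the same regression with an intercept (the mean
  directional pleiotropy), after orienting every SNP to β̂_X ≥ 0;
  t-reference with J−2 df; same SE scale floor.
- **Weighted median** — interpolated weighted median of the Wald ratios:
  with order statistics and standardized cumulative weights
  p_j = (S_j − w_j/2)/S_J, the estimate interpolates to p = 0.5. SE by
  parametric bootstrap (β̂s redrawn from normals with their SEs, default
  1,000 draws, seeded).
- **MBE** — normal-kernel density of the ratios, bandwidth
  φ × 0.9·min(SD, 1.4826·MAD)·J^(−1/5) with φ = 1 by default; the
  estimate is the density argmax on a uniform grid (ties resolved by the
  midpoint). The default is the simple (unweighted) mode; the weighted
  variant (inverse-variance kernel weights) is available via
  `weighted=True`. The simple variant was adopted because its larger
  sampling variability matches the known behaviour of the mode-based
  estimate relative to the regression methods, which the weighted variant
  largely erases; the choice affects SEs much more than point estimates.
  Bootstrap SE as for the median; each bootstrap draw gets its own
  bandwidth and a 512-point grid trimmed to the central 2–98% ratio
  range (resampled β̂_X near zero otherwise stretches the grid by orders
  of magnitude and destroys resolution where the mode lives).
- **MR-Robust** — MM-type robust regression through the origin on the
  precision-standardized data: Tukey biweight (c = 4.685,
  95% efficiency), initialized at the weighted median ratio, residual
  scale fixed at the initial MAD, IRLS to convergence. Sandwich SE with
  the scale floored at 1, mirroring the other regression methods (the
  standardized residuals have unit variance under homogeneity; without
  the floor the MAD's sampling error at J = 50 visibly inflates type I
  error).
- **Contamination mixture** — each ratio is valid, N(θ, s_j²), or
  invalid, N(0, s_j² + ψ²); SNPs take the likelier label at each grid θ
  and the profile log-likelihood is maximized over ≥ 5,000 grid points
  spanning the ratio range ± 3·max s_j. Defaults: ψ = 1.5 × SD of the
  ratios. The 95% CI collects grid points within χ²₁(0.95)/2 of the
  maximum; SE = CI width / (2·1.96); p-value by the likelihood ratio of
  θ = 0.
- **MR-RAPS** — solves Σ ψ(t_j)·∂t_j/∂θ = 0 with
  t_j = (β̂_Yj − θβ̂_Xj)/√(σ̂_Yj² + θ²σ̂_Xj² + τ²), Huber ψ (k = 1.345)
  and overdispersion by default; τ² solves the second moment equation
  Σ (ψ(t_j)t_j − δ)/σ_j² = 0 (δ = E[ψ(Z)Z], weighting by σ_j⁻² is this
  package's choice), alternating with the θ-equation to joint
  convergence. Roots are bracketed by a vectorized sign-change scan and
  polished by Brent. The SE uses the analytic sandwich of the adjusted
  profile score: the score terms reduce to t_j(β_Xj + e_j)/σ_j with e_j
  the component of the β̂_X error orthogonal to t_j, so
  Var(score) = E[ψ²]·Σ(β_Xj² + σ_Xj²)/σ_j² (estimated unbiasedly by
  β̂_Xj²) and information E[ψ′]·Σ(β̂_Xj² − σ_Xj²)/σ_j². τ² estimation
  uncertainty is not propagated.
- **MR-Lasso** — β̂_Yj = θβ̂_Xj + γ_j with an L1 penalty on the per-SNP
  pleiotropy intercepts, weights σ̂_Y⁻², solved by coordinate descent
  along a descending geometric λ path (50 points from just above the
  smallest all-zero λ). SNPs with γ̂_j = 0 form the retained set; the
  stopping rule keeps the largest retained set whose weighted
  heterogeneity statistic stays below the χ² upper quantile at level
  0.05/J (df = set size − 1); if no set passes, the least-heterogeneous
  retained set is used. The final estimate is IVW on the retained SNPs.

## Evaluation grid

A grid cell fixes (scenario, θ, J, invalid fraction, mechanism I,
mechanism II, effect). Per cell and method the grid reports bias (mean
estimate − θ), mean of estimated SEs, empirical SD of estimates, and the
rejection rate at nominal 0.05 (type I error at θ = 0, power otherwise).
Both readings of "SE" (average estimated vs empirical) are emitted so
either can be compared.

Seeding: a master seed is combined with a CRC-32 hash of the cell
coordinates into a `SeedSequence`; θ is excluded from the hash so cells
differing only in θ run on matched draws (paired comparisons of bias
across θ). Each replicate spawns independent child streams for the
coefficient draw, the two populations, the two selection draws and the
bootstrap estimators, so any cell or replicate is reproducible in
isolation.

Problem sizes: the package's default desk-scale profile is a population
of 100,000 per sample with 2,000 selected (preserving a ~2% selected
fraction) and 200 replicates per cell; the full-scale profile
(1,000,000 / 10,000 / 1,000 replicates) is configurable but long-running.
The acceptance script and the test suite use the desk-scale profile, with
25–50 replicates for the qualitative ordering checks whose effects are
large.

## What the generator does and does not emulate

It emulates: additive genetic effects at a common MAF, confounding,
direct and confounder-mediated pleiotropy, Bernoulli selection logistic
in X, Y and total allele count, and the two-sample design with disjoint
samples. It does not emulate linkage disequilibrium, MAF spectra, binary
traits (log-OR summary statistics), allele-harmonization errors, sample
overlap, or covariate-adjusted GWAS models. Conclusions from passing
tests therefore speak to selection/collider effects under an idealized
linear-Gaussian GWAS pair, not to artifacts arising from those omitted
features.

## Numerical choices and degenerate inputs

- Intercept calibration brackets are widened geometrically before Brent;
  non-convergence raises a calibration error.
- A constant genotype column in a selected sample raises a degenerate-
  regressor error that assembly propagates loudly (no silent NaNs).
- A β̂_X exactly zero makes the Wald ratio undefined and raises an error
  naming the SNP.
- All-equal ratios: the MBE bandwidth degenerates to zero and the common
  value is returned; MR-Lasso's λ_max is zero and the full-set IVW is
  returned.
- Kernel exponents are capped (exp(−40) floor) to avoid subnormal
  slowdowns; the MBE point estimate uses a 4,096-point grid over the full
  ratio range ± 3 bandwidths.
- The memory guard refuses genotype matrices above 5×10⁸ cells.

## Weak-instrument dilution at reduced sample sizes

With R² = 10% spread over J = 50 instruments, the mean per-SNP F
statistic is n·R²/J — about 4 at the desk-scale selected sample of
2,000, versus 20 at a 10,000 sample. Because E[β̂_X²] = β_X² + σ_X²,
methods that regress on the noisy β̂_X (IVW, Egger, robust, lasso) carry
a multiplicative regression-dilution factor of roughly
Σβ_X² / (Σβ_X² + Σσ_X²) ≈ 0.80 at desk scale: a true θ = 0.2 yields a
mean IVW estimate near 0.16. The effect is exactly proportional to θ, so
null-effect cells and type I error are untouched, and it shrinks with
sample size (factor ≈ 0.95 at a 10,000 sample). MR-RAPS models the β̂_X
error explicitly and is essentially free of this dilution. Comparisons
of bias across selection mechanisms — the point of the grid — are made
at matched sample size and are unaffected by the shared dilution factor.

## Known limitations

- The conmix SE is derived from the profile-likelihood CI width and can
  be conservative when the likelihood is flat.
- MR-RAPS assumes the moment constants of a correctly specified residual
  model; with gross model violations its sandwich can misstate the SE.
- MBE p-values inherit the bootstrap SE's heavy right tail; the method is
  markedly conservative under the null, consistent with its large SE.
- Power surfaces at full scale (10⁶ populations, 1,000 replicates) are
  supported but not exercised by the default test runs.
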