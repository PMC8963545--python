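# mrselect

Nonrandom selection — who ends up in a GWAS sample — is a collider-bias
hazard for two-sample Mendelian randomization (MR). If inclusion in the
exposure GWAS (sample I) or the outcome GWAS (sample II) depends on the
exposure *X*, the outcome *Y*, the instruments *G*, or combinations of
them, conditioning on selection can open the path *G* → *X* ← *U* → *Y*
and bias the causal estimate even for "pleiotropy-robust" estimators.
`mrselect` is a simulation laboratory for quantifying that damage: it
pairs an individual-level structural-model simulator and a logistic
selection layer with from-scratch implementations of eight summary-level
MR estimators, and evaluates bias, standard error, type I error and power
over a grid of selection mechanisms.

## The model

For individual *i* and SNPs *j* = 1..*J* (biallelic, MAF 0.3, mutually
independent):

```
G_ij ~ Binomial(2, 0.3)
U_i  = Σ_j φ_j G_ij + ε_U            (unmeasured confounder)
X_i  = Σ_j α_j G_ij + b U_i + ε_X    (exposure)
Y_i  = Σ_j γ_j G_ij + θ X_i + c U_i + ε_Y   (outcome)
```

with ε ~ N(0,1), b = c = 1, instrument strengths α_j ~ U(0, a) calibrated
so the direct genetic effects explain ~10% of Var(X), and pleiotropy
scenarios controlling γ (direct effects) and φ (confounder-mediated
effects) on an invalid subset of SNPs. Selection into each sample is
Bernoulli with

```
logit(π_i) = e0 + e_x X_i + e_y Y_i + e_g Σ_j G_ij
```

where the mechanism (one of X, Y, G, X+Y, G+X, G+Y, G+X+Y, none) decides
which coefficients equal the selection effect *e*; the intercept e0 is
calibrated so the expected selected fraction is comparable across
mechanisms, then exactly `n_target` individuals are subsampled.

Each replicate builds two independent populations sharing one draw of
(α, γ, φ), runs marginal per-SNP regressions of *X* in sample I and *Y*
in sample II, and hands the harmonized summary statistics
(β̂_Xj, σ̂_Xj, β̂_Yj, σ̂_Yj) to eight estimators: IVW, MR-Egger, weighted
median, mode-based estimate (MBE), MR-Robust, contamination mixture,
MR-RAPS and MR-Lasso.

## Worked example

```python
import numpy as np
from mrselect import (scenario, SelectionSpec, run_replicate)

spec = scenario(1, J=50, theta=0.2)          # no pleiotropy, true effect 0.2
res = run_replicate(
    spec,
    SelectionSpec("none", 0.0, n_target=2000),   # random selection, sample I
    SelectionSpec("Y", 1.0, n_target=2000),      # outcome-dependent, sample II
    n_population=100_000,
    seed=42,
)
for name, est in res.items():
    print(f"{name:16s} theta={est.theta_hat:+.3f}  se={est.se:.3f}  p={est.p_value:.3f}")
```

prints (seed 42):

```
ivw              theta=-0.020  se=0.054  p=0.717
egger            theta=-0.030  se=0.100  p=0.764
weighted_median  theta=+0.007  se=0.075  p=0.929
mbe              theta=+0.077  se=0.140  p=0.581
robust           theta=-0.018  se=0.052  p=0.730
conmix           theta=-0.043  se=0.200  p=1.000
raps             theta=-0.027  se=0.067  p=0.690
lasso            theta=-0.020  se=0.054  p=0.717
```

The true causal effect is 0.2, yet every estimate collapses toward zero
and no test rejects: outcome-dependent selection in sample II compresses
the variation
in *Y* among the selected, attenuating every per-SNP outcome association
and with it the causal estimate. Under the causal null (`theta=0`) the same
selection leaves all eight methods unbiased and correctly calibrated,
which is exactly why selection on *Y* is dangerous precisely when there
is an effect to find.

The same pipeline is scriptable from the shell:

```sh
mrselect simulate --theta 0.2 --mech-ii Y --effect 1 --out summary.csv
mrselect estimate summary.csv
mrselect grid config.yaml --out metrics.csv
mrselect report metrics.csv
```

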