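# mixmlsem

Clustering many groups on their **structural relations between latent
variables** while absorbing **measurement non-invariance** with group-level
random effects.

When a construct model (say, four factors measured by five questionnaire
items each) is administered in dozens of countries or classrooms, the
regression relations among the factors may differ across groups — but so may
the measurement itself (loadings, unique variances).  Naively clustering
groups on fitted SEM parameters mixes the two sources of heterogeneity.
This package implements a three-step *structural-after-measurement*
estimator that separates them:

1. **Measurement step** — per factor, a two-level CFA with the marker
   loading fixed to 1 in every group, normal random effects on non-invariant
   loadings (`lambda_jg = gamma_j + u_jg`, `u_jg ~ N(0, sigma_j)`), and
   log-normal random effects on non-invariant unique variances and on the
   factor variances.  Estimated by Gibbs sampling (Metropolis-within-Gibbs
   for the log-scale variance effects); the posterior mean and variance of
   each individual's factor score are carried forward.
2. **Croon correction** — the factor scores act as a single indicator per
   factor with per-group reliability `lambda_qg = var(E(f)) / phi_qg`,
   `phi_qg = var(E(f)) + E(var(f))`; the attenuation they introduce is
   removed algebraically,
   `Phi_g = Lambda_g^-1 (cov(F_g) - Theta_g) Lambda_g^-T`,
   yielding a bias-corrected factor covariance matrix per group.
3. **Mixture step** — groups are clustered by a K-component mixture over
   these covariance matrices: cluster-specific regression matrices `B_k`
   (recursive path model), group-specific residual covariances `Psi_gk`,
   implied `Phi_gk = (I - B_k)^-1 Psi_gk (I - B_k)^-T`, fitted by EM with
   multistart; each group's density is raised to its sample size.

The number of clusters is chosen by BIC (with the number of *groups* as the
sample size), AIC, and the CHull generalized scree test, all computed from a
single-indicator observed-data log-likelihood.  A synthetic-data generator
reproduces the factorial simulation design the method was validated on, and
the evaluation module scores cluster recovery (adjusted Rand index,
correct-classification rate after optimal label alignment) and parameter
recovery (RMSE of loadings, unique variances and regressions).

## Worked example

```python
from mixmlsem import (MixMLSEM, MeasurementSpec, StructuralSpec,
                      MCMCSettings, SimulationDesign, generate_dataset)
from mixmlsem.evaluate import evaluate_fit

design = SimulationDesign(n_groups=48, n_clusters=2, small_prop=0.0,
                          large_n=200, beta=0.4, reliability="high",
                          sampling="fixed", seed=21)
data, truth = generate_dataset(design)          # 48 groups x 200 rows x 20 items

model = MixMLSEM(data, MeasurementSpec.simulation_default(),
                 StructuralSpec.four_factor_default())
res = model.fit(k_range=range(1, 7), n_starts=50, seed=21,
                settings=MCMCSettings(chains=2, iterations=1200,
                                      burn_in=600, seed=21))
print(res.summary())
print(evaluate_fit(res.fits[2], truth, covs=res.covs).to_row())
```

Output (abridged):

```
model selection:
 K    loglik   P     BIC_G      AIC  ...
 1 -49335.94 628 101102.99 99927.88
 2 -49049.50 633 100549.47 99365.00
 3 -49049.50 638 100568.83 99375.00
 ...
selected K — BIC_G: 2, AIC: 2, CHull: 2

          pi  F1->F3  F2->F3  F1->F4  F3->F4
cluster
1        0.5  -0.000   0.402   0.403   0.403
2        0.5   0.404   0.401  -0.001   0.402

{'ari': 1.0, 'pct_correct': 1.0, 'uncertainty': 3.4e-11, ...}
```

The two generating clusters (one with the F1→F4 path zeroed, one with
F1→F3 zeroed, all other coefficients 0.4) are recovered exactly: every
group is classified correctly (ARI = 1), the estimated coefficients sit
within ±0.005 of the generating values, and all three selection criteria
pick K = 2.

A thin CLI mirrors the library:
`mixmlsem simulate | fit | select | evaluate | study` (see `--help`).

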