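# Methods

This note documents the model, the estimation choices, the synthetic-data
generator and the numerical decisions behind `mixmlsem`, in enough detail
to reproduce or audit any step.

## Model

Observed data are continuous item scores for individuals nested in G
groups.  Q constructs (factors) are each measured by a block of items
(single-factor measurement blocks).  Because interest is in covariance
structure only, items are centered within groups, which removes the mean
structure exactly (group intercepts drop out of every subsequent step).

**Measurement (Step 1).**  Within group g, `x_ng = lambda_g * eta_ng +
eps_ng`, `eps ~ N(0, Theta_g)` diagonal (optional 2x2 residual blocks for
declared item pairs).  Between groups:

- marker loading fixed to 1 in every group (identification: a unit change
  of the factor means the same thing everywhere);
- non-invariant loadings: `lambda_jg ~ N(gamma_j, sigma_j)`;
- invariant loadings: one shared parameter;
- non-invariant unique variances and all factor variances: normal random
  effects on the *log* of the variance (a normal distribution is not a
  sensible law for a variance, its log is);
- invariant unique variances: one shared parameter.

Which parameters are non-invariant is an input (the invariance pattern is
assumed known/pretested); `assess_random_effect_variance` offers an
advisory posterior check of any fitted random-effect variance.

**Croon correction (Step 2).**  The posterior mean factor scores are
treated as one observed indicator per factor.  Group-specific reliability
`lambda_qg = var(E(f_qng)) / phi_qg` with `phi_qg = var(E(f_qng)) +
E(var(f_qng))`; single-indicator unique variance
`phi_qg * lambda_qg * (1 - lambda_qg)`.  The corrected factor covariance
`Phi_g = Lambda_g^-1 (cov(F_g) - Theta_g) Lambda_g^-T` undoes the
attenuation of score-based covariances.  Deriving `phi_qg` from the scores
(rather than from the Step-1 factor-variance random effects) guarantees
`lambda_qg <= 1` and hence nonnegative unique variances; supplying an
external `phi_qg` that violates this raises an error.

**Mixture (Step 3).**  Groups belong to one of K latent clusters.  Given
membership, latent scores are MVN(0, `Phi_gk`) with
`Phi_gk = (I - B_k)^-1 Psi_gk (I - B_k)^-T`; `B_k` is the cluster-specific
regression matrix over a user-declared recursive path pattern, and
`Psi_gk` holds a free exogenous covariance block per group, free
endogenous residual variances per group, and zero endogenous residual
covariances — the minimal structure that keeps each group just-identified
given `B_k` while letting exogenous heterogeneity stay out of the
clustering.  The EM objective treats each group's corrected covariance as
a sufficient statistic, raising the component density to the group size.

## Estimation choices

**Step-1 sampler.**  Gibbs with conjugate updates for factor scores,
loadings, invariant variances and all hyper-means.  The log-scale variance
random effects have no conjugate conditional; each sweep combines (a) an
independence proposal from the inverse-gamma likelihood factor — its
acceptance ratio reduces to the log-normal prior ratio, so it mixes fast
wherever the data dominate — and (b) an adaptive random-walk step on the
log variance (step sizes tuned toward 44% acceptance during burn-in).
Three such sweeps run per iteration; they are cheap relative to the
factor-score update.  Priors (declared substitutes for generic
"non-informative" defaults, configurable in `MCMCSettings`): N(0, 10^2)
on loading means and log-scale means; half-Cauchy(1) on random-effect SDs
via the inverse-gamma auxiliary representation; IG(0.5, 0.5) on invariant
variances.  Defaults: 2 chains x 4000 iterations, 2000 burn-in; a fit is
flagged non-converged when any hyperparameter's split-chain R-hat exceeds
1.05.  Posterior factor-score means and variances are accumulated as
running moments across kept draws.  Fewer than 30 groups triggers a
warning (random-effect variances are weakly identified below that).

**Step-3 EM.**  The M-step estimates `B_k` by per-equation regression on
the membership-weighted pooled covariance `sum_g z_gk N_g Phi_g` — the
exact maximizer for a recursive model with diagonal endogenous residuals
fitted to a single covariance — and then recovers `Psi_gk` per group as
the structured part of `(I - B_k) Phi_g (I - B_k)^T`, flooring negative
endogenous residual variances at 1e-6 (floors are counted and reported).
Because `Psi_gk` is group-specific, the pooled B-update is not a
mathematical guarantee of ascent; a safeguard rolls a cluster's update
back to its previous `B_k` whenever it would lower the expected
complete-data log-likelihood, making the EM sequence monotone by
construction (rollbacks are counted; they are rare).  Multistart: 50
random uniform hard partitions by default, up to 3 redraws per start on
degenerate or emptied clusters; the highest final log-likelihood wins.
Convergence: absolute log-likelihood change below 1e-6, at most 500
iterations.  With K = 1 the fit equals a plain multigroup path model on
the pooled covariance.

**Model selection.**  BIC and AIC use a single-indicator observed-data
log-likelihood of the factor scores (evaluating the mixture density of
each group's score matrix under
`Lambda_hat_g Phi_gk Lambda_hat_g + Theta_hat_g`).  The parameter count is
`(K-1) + K * |free paths| + G * |free Psi cells| + 2 Q G` (one `Psi` set
per group — the model assigns each group to one cluster — plus the
single-indicator loadings and unique variances).  BIC with the number of
groups as sample size (`BIC_G`) is the primary criterion; `BIC_N` is
emitted as a secondary column.  The CHull scree test forms the upper
convex hull of (P, logL), excluding models whose fit is strictly worse
than a simpler model's and keeping collinear points (log-likelihoods
within a 1e-9 relative tolerance are snapped to equality first — EM runs
with duplicated clusters agree only to floating-point noise); the scree ratio of
each interior hull model is the ratio of adjacent per-parameter fit gains.
A zero fit gain after a positive one yields an *infinite* ratio; because
an infinite maximal ratio marks where fit stops improving rather than an
elbow, the programmatic answer falls back to the second-largest ratio when
a finite one exists, and the full ratio table plus hull flags are always
emitted for visual inspection.  CHull cannot select the least complex
model, and the observed log-likelihood need not increase with K (EM
maximizes the covariance criterion, not this one), in which case the
affected models drop off the hull — both outcomes are reported, not
errors.  Information-criterion ties break toward smaller K.

## Synthetic-data generator

The generator reproduces the validation study's conditions; its defaults
*are* those conditions, not tuning knobs.

- 4 factors x 5 items; marker loading 1; items 4-5 invariant with loading
  0.6 / unique variance 0.4 (high reliability) or 0.4 / 0.6 (low); items
  2-3 non-invariant with loadings ~ N(0.6 or 0.4, variance 0.1) and unique
  variances log-normal with log-SD 0.25 and log-mean -0.948 (high) or
  -0.542 (low); item 1's unique variance invariant at 0.4 / 0.6.
- K balanced clusters (K in {2, 4}); cluster k zeroes one of the four
  coefficients beta1: F1->F4, beta2: F1->F3, beta3: F2->F3, beta4: F3->F4
  and sets the rest to beta in {0.2, 0.3, 0.4}, so any two clusters differ
  in exactly two coefficients by magnitude beta.
- exogenous (F1, F2) covariance block per group: Wishart with df = 66 and
  scale (0.952/66) I.  These two numbers are the one place the design had
  to be inferred: only the realized moments are reported (variances with
  mean 0.952 and SD 0.166, covariance with SD 0.117), and this df/scale
  pair reproduces all three simultaneously (mean m, diag SD m*sqrt(2/df),
  offdiag SD m/sqrt(df)).  Both are exposed as parameters.
- endogenous total variances Var(F3), Var(F4): log-normal with log-mean 0;
  the log-SD is not reported and defaults to 0.25, matching the generator's
  other variance law; exposed as a parameter.  Residual variances are
  total minus explained (using the path algebra of the recursive model);
  draws implying a negative residual variance are redrawn (totals only),
  capped at 100 attempts per group — silent truncation would bias the
  design.
- group sizes: within each cluster, `round(prop * G/K)` groups get the
  small size (25 or 50), the rest the large size (100 or 200).
- `fixed` sampling recolours a whitened sample so the empirical covariance
  (denominator N_g, consistently used in Step 2) equals the model-implied
  covariance to ~1e-15 and means are exactly 0 — the "whole group
  observed" regime; `random` sampling draws i.i.d. MVN rows.  Fixed
  sampling needs N_g >= 21 (items + 1).
- one seed drives everything through spawned per-group streams, so
  datasets are bit-reproducible and generation could be parallelized.

What the generator does **not** emulate: unbalanced clusters, mean
(intercept) differences between groups, ordinal items, cross-loadings, and
residual covariances between items.  Passing tests therefore demonstrate
recovery under a correctly specified invariance pattern with continuous
multivariate-normal data; they say nothing about robustness to
misspecified measurement models.

## Evaluation metrics

Adjusted Rand index on the modal (hard) partition; correct-classification
rate after aligning labels by maximum-assignment on the confusion matrix
(the alignment rule was left open in the source material; optimal
assignment is the standard resolution of label switching and the same map
is reused for the per-coefficient regression RMSE).  Classification
uncertainty is the mean of `1 - max_k z_gk`.  Measurement RMSEs average
squared errors over groups and *non-invariant* parameters only.  A
"one-cluster collapse" (all groups modally in one cluster) is recorded,
not suppressed — it is a real failure mode of the method in hard
conditions.  The local-maximum proxy refits from the true partition and
flags the multistart solution when it trails the proxy by more than 0.001.

## Problem sizes used in the shipped checks

The full validation design (48,000 datasets) is far beyond a desk run.
The shipped checks use, as this package's own scaled-down choices:

- Step-1 recovery: 5-6 datasets per condition, sampler at 2 chains x
  1000-1500 iterations (half burn-in);
- cluster recovery: a stratified 30-cell subset (full cross of sampling x
  small-group proportion x beta at low reliability, K/G/sizes rotated),
  one replicate per cell, plus 36 + 24 fixed-sampling runs for the
  small-group-proportion contrast;
- model selection: the same 30 runs fitted with K = 1..6, 50 starts each.

Monte-Carlo tolerances in the tests reflect these counts.  Full-scale
settings (2 x 4000 iterations, arbitrary grids, any replication count)
remain available through `MCMCSettings` and `run_simulation_study`.

## Known limitations

- Residual-covariance pairs in Step 1 require invariant loadings and
  unique variances for the paired items (sufficient for the empirical
  model the feature exists for); random loadings within a pair are not
  implemented.
- The `Psi_gk` recovery step is a declared approximation: it reconstructs
  each group's residual covariance structurally from `B_k` with a
  nonnegativity floor rather than reproducing an external bias-correction
  algorithm in closed form.
- The mixture clusters on regression structure only; factor means are
  removed by centering, and group-level moderators of membership are out
  of scope.
- The CHull answer is advisory where ratios are infinite or the hull is
  degenerate; the emitted table supports the recommended visual check.
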