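# File schemas (v1)

All artifacts are plain text (CSV, JSON, YAML).  Schemas are versioned by
this document; the current version is **1**.

## Item data CSV

One row per individual.

| column | type | meaning |
|---|---|---|
| `group` | int/str | group identifier |
| `id` | int | individual within group (optional) |
| `y1..yJ` | float | item scores (20 items in the study design) |

Written by `mixmlsem simulate` / `simulate.write_dataset`; read by
`MixMLSEM.from_csv` and `PipelineConfig.data_path`.

## Ground-truth JSON (`truth.json`)

Keys: `cluster_of_group` (G ints), `group_sizes` (G ints), `B_true`
(K×Q×Q), `Lambda_true`, `Theta_true` (G×Q×J_q), `Psi_true`, `Phi_true`
(G×Q×Q), `Sigma_true` (G×J×J), `design` (SimulationDesign fields),
`resample_events` (int).

## Factor-score CSV (`factor_scores.csv`)

`group`, `id`, then `F*_mean`, `F*_sd` per factor — posterior mean and SD
of each individual's factor score, means re-centered per group.

## Measurement-block JSON (`mlcfa_<factor>.json`)

Posterior summaries per factor block: hyperparameter tables
(`gamma_lambda`, `sigma_lambda`, `invariant_loadings`, `gamma_theta`,
`sigma_theta`, `invariant_uniquenesses`, `factor_variance`; each item →
`{mean, sd}`), group-level posterior means (`group_loadings`,
`group_uniquenesses`, `group_factor_variances`), split R-hat
`diagnostics`, `converged` flag and the `settings` used.

## Covariance bundle JSON (`group_factor_covs.json`)

The Step-2 → Step-3 contract: `groups`, `factors`, `phi_s2` (G×Q×Q
corrected covariances), `cov_F` (raw score covariances), `n_g` (group
sizes), `repaired` (groups whose matrix needed a positive-definiteness
repair).  Single-indicator parameters are written alongside as
`single_indicator_params.csv` (`group, factor, lambda, theta, phi`).

## Mixture fit JSON (`mixture_k<K>.json`)

`pi` (K), `B` (K×Q×Q), `z` (G×K posterior memberships), `loglik`
(covariance criterion), `loglik_obs` (single-indicator observed),
`n_iter`, `converged`, `start_id`.

## Selection table CSV (`selection_table.csv`)

`K, loglik, P, BIC_G, BIC_N, AIC, on_hull, scree_ratio` — one row per
fitted number of clusters.

## Pipeline config YAML (`mixmlsem fit`)

```yaml
data_path: items.csv
measurement:
  factors:
    F1: {items: [y1, y2, y3, y4, y5], marker: y1,
         random_loadings: [y2, y3], random_uniquenesses: [y2, y3],
         random_factor_variance: true}
    # ... one entry per factor
  residual_cov_pairs: []          # e.g. [[y1, y2]]
structural:
  factor_order: [F1, F2, F3, F4]
  paths: [[F1, F3], [F2, F3], [F1, F4], [F3, F4]]
  exogenous: [F1, F2]
k_min: 1
k_max: 6
n_starts: 50
seed: 0
mcmc: {chains: 2, iterations: 4000, burn_in: 2000}
output_dir: out
```

## Design-grid YAML (`mixmlsem study`)

A YAML list; each entry holds `SimulationDesign` fields:

```yaml
- {n_groups: 48, n_clusters: 2, small_n: 25, large_n: 100,
   small_prop: 0.5, beta: 0.3, reliability: high, sampling: fixed}
```

## Study results CSV

One row per (cell, replicate): the design fields, `cell`, `replicate`,
`seed`, the recovery metrics (`ari`, `pct_correct`, `uncertainty`,
`rmse_lambda`, `rmse_theta`, `rmse_beta1..4`, `one_cluster_collapse`,
`local_maximum`), `step1_converged`, selection outcomes in study-2 mode
(`selected_BIC_G/AIC/CHull`, `correct_*`), and `failed`/`error`/
`elapsed_s` bookkeeping.

## Run manifest (`manifest.json`)

Seeds, cluster range, multistart count, tolerances, sampler settings,
data dimensions and elapsed time — sufficient to reproduce the run
bit-for-bit with the same package version.
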