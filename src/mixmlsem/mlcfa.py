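"""Step 1: multilevel CFA per factor with random measurement effects (MCMC).

Each factor (measurement block) is fitted separately.  Within group g the
centered item scores follow ``x_ng = lambda_g * eta_ng + eps_ng`` with
diagonal unique variances; between groups, non-invariant loadings carry
normal random effects, while non-invariant unique variances and the factor
variances are modeled on the log scale (a normal distribution on the log of
the variance).  Invariant parameters are single shared coefficients; the
marker loading is fixed to one in every group, which fixes the latent scale
identically across groups.

Estimation is Gibbs sampling with conditionally conjugate updates for
loadings, factor scores, invariant variances and all hyper-means, and
Metropolis-within-Gibbs random-walk updates (adapted during burn-in) for the
log-scale variance random effects, which have no conjugate form.  Priors:
Normal(0, 10^2) on loading means and log-scale means, half-Cauchy(1) on
random-effect SDs (via the inverse-gamma auxiliary representation), and
inverse-gamma(0.5, 0.5) on invariant variances — declared substitutes for
generic "non-informative" defaults.

The per-individual posterior mean and variance of the factor score are the
quantities consumed by Step 2.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .specs import MCMCSettings, MeasurementSpec

logger = logging.getLogger(__name__)

__all__ = [
    "MultilevelCFA",
    "MLCFAResults",
    "center_within_group",
    "fit_mlcfa_block",
    "fit_all_blocks",
    "extract_factor_scores",
    "assess_random_effect_variance",
]


def center_within_group(data: pd.DataFrame, item_columns=None) -> pd.DataFrame:
    """Center every item within each group (exact zero group means).

    Idempotent; removes the mean structure so that group-specific intercepts
    drop out of the model.  Groups with fewer than two rows are rejected.
    """
    if "group" not in data.columns:
        raise ValueError("data must have a 'group' column")
    counts = data.groupby("group").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 rows cannot be centered: {bad}")
    if item_columns is None:
        item_columns = [c for c in data.columns
                        if c not in ("group", "id") and pd.api.types.is_numeric_dtype(data[c])]
    out = data.copy()
    out[item_columns] = (data.groupby("group")[item_columns]
                         .transform(lambda s: s - s.mean()))
    return out


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, iterations); each chain is split in half.
    """
    c, t = draws.shape
    half = t // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class MLCFAResults:
    """Posterior summaries for one measurement block.

    Group-level arrays are ordered by the sorted group labels in
    ``groups``; ``group_loadings``/``group_uniquenesses`` have one column
    per item of the block.
    """

    factor: str
    items: list
    groups: np.ndarray
    settings: MCMCSettings

    gamma_lambda: pd.DataFrame          # random-loading means (item -> mean/sd)
    sigma_lambda: pd.DataFrame          # random-loading variances (item -> mean/sd)
    invariant_loadings: pd.DataFrame
    gamma_theta: pd.DataFrame           # log-scale uniqueness means
    sigma_theta: pd.DataFrame
    invariant_uniquenesses: pd.DataFrame
    factor_variance: pd.DataFrame       # log-scale mean/variance of phi (or shared phi)

    group_loadings: np.ndarray          # (G, J) posterior means
    group_uniquenesses: np.ndarray      # (G, J) posterior means
    group_factor_variances: np.ndarray  # (G,) posterior means

    factor_scores: pd.DataFrame         # group, id, mean, sd per individual
    diagnostics: dict                   # hyperparameter -> split R-hat
    converged: bool
    residual_covs: dict = field(default_factory=dict)
    _variance_draws: dict = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        """Serialize the posterior summaries (without per-individual scores;
        those go to the factor-score CSV)."""
        import json

        payload = {
            "factor": self.factor,
            "items": list(self.items),
            "groups": np.asarray(self.groups).tolist(),
            "gamma_lambda": self.gamma_lambda.to_dict(orient="index"),
            "sigma_lambda": self.sigma_lambda.to_dict(orient="index"),
            "invariant_loadings": self.invariant_loadings.to_dict(orient="index"),
            "gamma_theta": self.gamma_theta.to_dict(orient="index"),
            "sigma_theta": self.sigma_theta.to_dict(orient="index"),
            "invariant_uniquenesses":
                self.invariant_uniquenesses.to_dict(orient="index"),
            "factor_variance": self.factor_variance.to_dict(orient="index"),
            "group_loadings": self.group_loadings.tolist(),
            "group_uniquenesses": self.group_uniquenesses.tolist(),
            "group_factor_variances": self.group_factor_variances.tolist(),
            "diagnostics": {k: (None if np.isnan(v) else float(v))
                            for k, v in self.diagnostics.items()},
            "converged": bool(self.converged),
            "settings": self.settings.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def summary(self) -> str:
        lines = [
            f"Multilevel CFA block: factor {self.factor}",
            "=" * 46,
            f"groups: {len(self.groups)}   individuals: {len(self.factor_scores)}",
            f"chains: {self.settings.chains} x {self.settings.iterations} "
            f"(burn-in {self.settings.burn_in})   converged: {self.converged}",
            "",
            "random loading means (gamma):",
            self.gamma_lambda.round(4).to_string(),
            "random loading variances (sigma):",
            self.sigma_lambda.round(4).to_string(),
        ]
        if len(self.invariant_loadings):
            lines += ["invariant loadings:", self.invariant_loadings.round(4).to_string()]
        if len(self.invariant_uniquenesses):
            lines += ["invariant unique variances:",
                      self.invariant_uniquenesses.round(4).to_string()]
        worst = max(self.diagnostics.values()) if self.diagnostics else np.nan
        lines += ["", f"worst split R-hat: {worst:.3f}"]
        return "\n".join(lines)


class MultilevelCFA:
    """Two-level CFA model for a single measurement block.

    Parameters
    ----------
    data : DataFrame
        Columns ``group``, optionally ``id``, and the block's items,
        centered within groups (see :func:`center_within_group`).
    spec : MeasurementSpec
    factor : str
        Which block of ``spec`` to fit.
    """

    def __init__(self, data: pd.DataFrame, spec: MeasurementSpec, factor: str):
        if factor not in spec.factor_blocks:
            raise ValueError(f"unknown factor {factor!r}")
        self.spec = spec
        self.factor = factor
        self.items = spec.items_of(factor)
        missing = [c for c in self.items if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks item columns {missing}")
        df = data.sort_values("group", kind="stable").reset_index(drop=True)
        means = df.groupby("group")[self.items].mean().to_numpy()
        if np.abs(means).max() > 1e-8:
            raise ValueError("items are not centered within groups; "
                             "call center_within_group first")
        self._df = df
        self.groups, self._gidx = np.unique(df["group"].to_numpy(), return_inverse=True)
        self.n_groups = len(self.groups)
        if self.n_groups < 30:
            logger.warning(
                "only %d groups: random-effect estimates may be unreliable "
                "(at least 30-50 groups are recommended)", self.n_groups)
        self.X = df[self.items].to_numpy(dtype=float)
        self.group_sizes = np.bincount(self._gidx, minlength=self.n_groups)
        # rows are sorted by group, so reduceat segment starts suffice
        self._starts = np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]])

        items = self.items
        self.marker = items.index(spec.marker_items[factor])
        self.rand_load = [items.index(i) for i in spec.random_loading_items[factor]]
        self.rand_uniq = [items.index(i) for i in spec.random_uniqueness_items[factor]]
        self.inv_load = [j for j in range(len(items))
                         if j != self.marker and j not in self.rand_load]
        self.pairs = []
        for a, b in spec.residual_cov_pairs:
            if a in items and b in items:
                ja, jb = items.index(a), items.index(b)
                if ja in self.rand_uniq or jb in self.rand_uniq:
                    raise ValueError(
                        f"residual covariance pair ({a}, {b}): members must have "
                        "invariant unique variances")
                if ja in self.rand_load or jb in self.rand_load:
                    raise NotImplementedError(
                        f"residual covariance pair ({a}, {b}): members with "
                        "random loadings are not supported")
                self.pairs.append((ja, jb))
        paired = {j for p in self.pairs for j in p}
        self.inv_uniq = [j for j in range(len(items))
                         if j not in self.rand_uniq and j not in paired]
        self.random_phi = bool(spec.random_factor_variance[factor])

    # ----- sampler -------------------------------------------------------

    def _initial_state(self, rng):
        X, gidx, G = self.X, self._gidx, self.n_groups
        J = X.shape[1]
        starts = self._starts
        ng = self.group_sizes.astype(float)
        xm = X[:, self.marker]
        vm = np.add.reduceat(xm ** 2, starts) / ng            # marker variance per group
        sxm = np.add.reduceat(X * xm[:, None], starts, axis=0) / ng[:, None]
        phi = np.clip(0.6 * vm, 0.05, None)
        lam = np.clip(sxm / np.maximum(vm, 0.05)[:, None], -3.0, 3.0)
        lam[:, self.marker] = 1.0
        lam *= np.exp(0.05 * rng.standard_normal(lam.shape))
        lam[:, self.marker] = 1.0
        vx = np.add.reduceat(X ** 2, starts, axis=0) / ng[:, None]
        theta = np.clip(vx - lam ** 2 * phi[:, None], 0.05, None)
        state = {
            "lam": lam, "theta": theta, "phi": phi,
            "gam_lam": {j: float(lam[:, j].mean()) for j in self.rand_load},
            "sig_lam": {j: 0.05 for j in self.rand_load},
            "a_lam": {j: 1.0 for j in self.rand_load},
            "gam_th": {j: float(np.log(theta[:, j]).mean()) for j in self.rand_uniq},
            "sig_th": {j: 0.05 for j in self.rand_uniq},
            "a_th": {j: 1.0 for j in self.rand_uniq},
            "gam_phi": float(np.log(phi).mean()),
            "sig_phi": 0.05,
            "a_phi": 1.0,
            "pair_cov": {p: np.diag(theta[:, list(p)].mean(axis=0)) for p in self.pairs},
        }
        # collapse invariant columns to shared values
        for j in self.inv_load:
            state["lam"][:, j] = lam[:, j].mean()
        for j in self.inv_uniq:
            state["theta"][:, j] = theta[:, j].mean()
        if not self.random_phi:
            state["phi"][:] = phi.mean()
        # MH step sizes per (item, group) / group
        state["step_th"] = {j: np.full(G, 0.3) for j in self.rand_uniq}
        state["step_phi"] = np.full(G, 0.3)
        return state

    def _theta_matrices(self, state):
        """(G, J, J) residual covariance matrices (only when pairs exist)."""
        G, J = self.n_groups, len(self.items)
        Th = np.zeros((G, J, J))
        idx = np.arange(J)
        Th[:, idx, idx] = state["theta"]
        for (ja, jb), cov in state["pair_cov"].items():
            Th[:, ja, ja] = cov[0, 0]
            Th[:, jb, jb] = cov[1, 1]
            Th[:, ja, jb] = Th[:, jb, ja] = cov[0, 1]
        return Th

    def _draw_eta(self, state, rng):
        X, gidx = self.X, self._gidx
        lam, theta, phi = state["lam"], state["theta"], state["phi"]
        if not self.pairs:
            ratio = lam / theta                        # (G, J)
            prec_g = (lam * ratio).sum(axis=1) + 1.0 / phi
            a = ratio[gidx]
            mean = (X * a).sum(axis=1) / prec_g[gidx]
            sd = 1.0 / np.sqrt(prec_g[gidx])
        else:
            Th = self._theta_matrices(state)
            Tinv = np.linalg.inv(Th)
            w = np.einsum("gjk,gk->gj", Tinv, lam)     # (G, J)
            prec_g = np.einsum("gj,gj->g", lam, w) + 1.0 / phi
            mean = (X * w[gidx]).sum(axis=1) / prec_g[gidx]
            sd = 1.0 / np.sqrt(prec_g[gidx])
        return mean + sd * rng.standard_normal(len(mean))

    @staticmethod
    def _mh_log_variance(cur: np.ndarray, ssq: np.ndarray, ng: np.ndarray,
                         gamma: float, sigma: float, step: np.ndarray,
                         acc: np.ndarray, rng) -> np.ndarray:
        """One MH sweep for per-group variances with a log-normal random effect.

        The conditional ``p(v) ~ v^(-n/2) exp(-ssq/(2v)) * LN(v; gamma, sigma)``
        has no conjugate form.  Two proposals are combined: an independence
        draw from the inverse-gamma likelihood factor (its acceptance ratio
        reduces to the log-normal prior ratio, so it mixes fast whenever the
        likelihood dominates) followed by an adaptive random walk on log v
        (which covers the prior-dominated regime; its acceptance feeds the
        burn-in step-size adaptation).
        """
        def logp(v):
            return (-0.5 * ng * v - 0.5 * ssq * np.exp(-v)
                    - 0.5 * (v - gamma) ** 2 / sigma)

        n_sweeps = 3  # cheap relative to the factor-score update; helps mixing
        for sweep in range(n_sweeps):
            # independence proposal: v' ~ IG(n/2, ssq/2)
            prop = 0.5 * ssq / rng.gamma(0.5 * ng)
            lr = (-0.5 * (np.log(prop) - gamma) ** 2 / sigma
                  + 0.5 * (np.log(cur) - gamma) ** 2 / sigma)
            take = np.log(rng.random(len(cur))) < lr
            cur = np.where(take, prop, cur)
            # adaptive random walk on the log scale
            u = np.log(cur)
            prop_u = u + step * rng.standard_normal(len(cur))
            accept = np.log(rng.random(len(cur))) < logp(prop_u) - logp(u)
            if sweep == 0:
                acc += accept
            cur = np.exp(np.where(accept, prop_u, u))
        return cur

    def _run_chain(self, settings: MCMCSettings, chain: int):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(settings.seed), 23, chain,
                                    zlib.crc32(str(self.factor).encode())]))
        X, gidx, starts = self.X, self._gidx, self._starts
        N, J = X.shape
        G = self.n_groups
        ng = self.group_sizes.astype(float)
        s = self._initial_state(rng)
        A_hc = settings.prior_scale_hc
        m_prec = 1.0 / settings.prior_mean_sd ** 2
        ig_a, ig_b = settings.prior_ig_shape, settings.prior_ig_rate

        kept = (settings.iterations - settings.burn_in) // settings.thinning
        acc = {("theta", j): np.zeros(G) for j in self.rand_uniq}
        acc[("phi", None)] = np.zeros(G)
        n_adapt_window = 50

        eta_sum = np.zeros(N)
        eta_sq = np.zeros(N)
        lam_sum = np.zeros((G, J))
        th_sum = np.zeros((G, J))
        phi_sum = np.zeros(G)
        hyper_names = self._hyper_names()
        hyper_draws = {name: np.empty(kept) for name in hyper_names}
        pair_sum = {p: np.zeros((2, 2)) for p in self.pairs}
        k = 0

        def invgamma(shape, rate):
            return rate / rng.gamma(shape)

        for it in range(settings.iterations):
            eta = self._draw_eta(s, rng)
            S_e2 = np.add.reduceat(eta ** 2, starts)
            S_xe = np.add.reduceat(X * eta[:, None], starts, axis=0)

            lam, theta, phi = s["lam"], s["theta"], s["phi"]
            # random loadings (per group, conjugate)
            for j in self.rand_load:
                prec = S_e2 / theta[:, j] + 1.0 / s["sig_lam"][j]
                mean = (S_xe[:, j] / theta[:, j]
                        + s["gam_lam"][j] / s["sig_lam"][j]) / prec
                lam[:, j] = mean + rng.standard_normal(G) / np.sqrt(prec)
            # invariant loadings (shared, conjugate); paired items jointly
            paired = {j for p in self.pairs for j in p}
            for j in self.inv_load:
                if j in paired:
                    continue
                prec = (S_e2 / theta[:, j]).sum() + m_prec
                mean = (S_xe[:, j] / theta[:, j]).sum() / prec
                lam[:, j] = mean + rng.standard_normal() / np.sqrt(prec)
            for (ja, jb), cov in list(s["pair_cov"].items()):
                # joint conjugate update of the pair's free (invariant) loadings
                free = [j for j in (ja, jb) if j in self.inv_load]
                if not free:
                    continue
                Sinv = np.linalg.inv(cov)
                pos = {ja: 0, jb: 1}
                fidx = [pos[j] for j in free]
                cidx = [pos[j] for j in (ja, jb) if j not in free]
                e2 = S_e2.sum()
                sxe = S_xe[:, [ja, jb]].sum(axis=0)       # sum_n eta_n x_pair,n
                rhs = (Sinv @ sxe)[fidx]
                if cidx:
                    lam_fixed = np.array([lam[0, j] for j in (ja, jb) if j not in free])
                    rhs -= e2 * (Sinv[np.ix_(fidx, cidx)] @ lam_fixed)
                prec = e2 * Sinv[np.ix_(fidx, fidx)] + m_prec * np.eye(len(free))
                covp = np.linalg.inv(prec)
                draw = rng.multivariate_normal(covp @ rhs, covp)
                for p_, j in enumerate(free):
                    lam[:, j] = draw[p_]

            # residuals and unique variances
            resid = X - eta[:, None] * lam[gidx]
            RSS = np.add.reduceat(resid ** 2, starts, axis=0)   # (G, J)
            for j in self.inv_uniq:
                val = invgamma(ig_a + 0.5 * N, ig_b + 0.5 * RSS[:, j].sum())
                theta[:, j] = val
            for j in self.rand_uniq:
                theta[:, j] = self._mh_log_variance(
                    theta[:, j], RSS[:, j], ng, s["gam_th"][j], s["sig_th"][j],
                    s["step_th"][j], acc[("theta", j)], rng)
            for p in self.pairs:
                ja, jb = p
                scatter = np.empty((2, 2))
                scatter[0, 0] = RSS[:, ja].sum()
                scatter[1, 1] = RSS[:, jb].sum()
                cross = np.sum(resid[:, ja] * resid[:, jb])
                scatter[0, 1] = scatter[1, 0] = cross
                df_post = 3 + N
                S_post = np.eye(2) + scatter
                # inverse-Wishart draw via Wishart of the inverse scale
                L = np.linalg.cholesky(np.linalg.inv(S_post))
                a11 = np.sqrt(rng.chisquare(df_post))
                a22 = np.sqrt(rng.chisquare(df_post - 1))
                n21 = rng.standard_normal()
                Amat = np.array([[a11, 0.0], [n21, a22]])
                W = L @ Amat @ Amat.T @ L.T
                s["pair_cov"][p] = np.linalg.inv(W)
                theta[:, ja] = s["pair_cov"][p][0, 0]
                theta[:, jb] = s["pair_cov"][p][1, 1]

            # factor variance
            if self.random_phi:
                s["phi"] = self._mh_log_variance(
                    s["phi"], S_e2, ng, s["gam_phi"], s["sig_phi"],
                    s["step_phi"], acc[("phi", None)], rng)
            else:
                s["phi"][:] = invgamma(ig_a + 0.5 * N, ig_b + 0.5 * S_e2.sum())

            # hyperparameters: normal means, half-Cauchy variances (aux IG)
            for j in self.rand_load:
                prec = G / s["sig_lam"][j] + m_prec
                mean = lam[:, j].sum() / s["sig_lam"][j] / prec
                s["gam_lam"][j] = mean + rng.standard_normal() / np.sqrt(prec)
                dev = np.sum((lam[:, j] - s["gam_lam"][j]) ** 2)
                s["sig_lam"][j] = invgamma(0.5 * (G + 1), 1.0 / s["a_lam"][j] + 0.5 * dev)
                s["a_lam"][j] = invgamma(1.0, 1.0 / A_hc ** 2 + 1.0 / s["sig_lam"][j])
            for j in self.rand_uniq:
                u = np.log(theta[:, j])
                prec = G / s["sig_th"][j] + m_prec
                mean = u.sum() / s["sig_th"][j] / prec
                s["gam_th"][j] = mean + rng.standard_normal() / np.sqrt(prec)
                dev = np.sum((u - s["gam_th"][j]) ** 2)
                s["sig_th"][j] = invgamma(0.5 * (G + 1), 1.0 / s["a_th"][j] + 0.5 * dev)
                s["a_th"][j] = invgamma(1.0, 1.0 / A_hc ** 2 + 1.0 / s["sig_th"][j])
            if self.random_phi:
                v = np.log(s["phi"])
                prec = G / s["sig_phi"] + m_prec
                mean = v.sum() / s["sig_phi"] / prec
                s["gam_phi"] = mean + rng.standard_normal() / np.sqrt(prec)
                dev = np.sum((v - s["gam_phi"]) ** 2)
                s["sig_phi"] = invgamma(0.5 * (G + 1), 1.0 / s["a_phi"] + 0.5 * dev)
                s["a_phi"] = invgamma(1.0, 1.0 / A_hc ** 2 + 1.0 / s["sig_phi"])

            # burn-in adaptation of MH steps (target acceptance ~0.44)
            if it < settings.burn_in and (it + 1) % n_adapt_window == 0:
                for key, counts in acc.items():
                    rate = counts / n_adapt_window
                    fac = np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    if key[0] == "theta":
                        s["step_th"][key[1]] = np.clip(s["step_th"][key[1]] * fac,
                                                       0.01, 3.0)
                    else:
                        s["step_phi"] = np.clip(s["step_phi"] * fac, 0.01, 3.0)
                    counts[:] = 0.0

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
                eta_sum += eta
                eta_sq += eta ** 2
                lam_sum += lam
                th_sum += theta
                phi_sum += s["phi"]
                for p in self.pairs:
                    pair_sum[p] += s["pair_cov"][p]
                self._record_hyper(s, hyper_draws, k)
                k += 1

        return {
            "kept": k, "eta_sum": eta_sum, "eta_sq": eta_sq,
            "lam_sum": lam_sum, "th_sum": th_sum, "phi_sum": phi_sum,
            "hyper": hyper_draws, "pair_sum": pair_sum,
        }

    def _hyper_names(self):
        names = []
        for j in self.rand_load:
            names += [f"gamma_lambda[{self.items[j]}]", f"sigma_lambda[{self.items[j]}]"]
        for j in self.inv_load:
            names.append(f"lambda[{self.items[j]}]")
        for j in self.rand_uniq:
            names += [f"gamma_theta[{self.items[j]}]", f"sigma_theta[{self.items[j]}]"]
        for j in self.inv_uniq:
            names.append(f"theta[{self.items[j]}]")
        if self.random_phi:
            names += ["gamma_phi", "sigma_phi"]
        else:
            names.append("phi")
        return names

    def _record_hyper(self, s, draws, k):
        for j in self.rand_load:
            draws[f"gamma_lambda[{self.items[j]}]"][k] = s["gam_lam"][j]
            draws[f"sigma_lambda[{self.items[j]}]"][k] = s["sig_lam"][j]
        for j in self.inv_load:
            draws[f"lambda[{self.items[j]}]"][k] = s["lam"][0, j]
        for j in self.rand_uniq:
            draws[f"gamma_theta[{self.items[j]}]"][k] = s["gam_th"][j]
            draws[f"sigma_theta[{self.items[j]}]"][k] = s["sig_th"][j]
        for j in self.inv_uniq:
            draws[f"theta[{self.items[j]}]"][k] = s["theta"][0, j]
        if self.random_phi:
            draws["gamma_phi"][k] = s["gam_phi"]
            draws["sigma_phi"][k] = s["sig_phi"]
        else:
            draws["phi"][k] = s["phi"][0]

    def fit(self, settings: MCMCSettings | None = None) -> MLCFAResults:
        """Run the sampler and summarize the posteriors."""
        if settings is None:
            settings = MCMCSettings()
        chains = [self._run_chain(settings, c) for c in range(settings.chains)]
        kept_total = sum(c["kept"] for c in chains)

        eta_sum = sum(c["eta_sum"] for c in chains)
        eta_sq = sum(c["eta_sq"] for c in chains)
        eta_mean = eta_sum / kept_total
        eta_var = np.maximum(eta_sq / kept_total - eta_mean ** 2, 1e-12)

        lam_mean = sum(c["lam_sum"] for c in chains) / kept_total
        th_mean = sum(c["th_sum"] for c in chains) / kept_total
        phi_mean = sum(c["phi_sum"] for c in chains) / kept_total

        hyper = {name: np.stack([c["hyper"][name] for c in chains])
                 for name in chains[0]["hyper"]}
        diagnostics = {name: _split_rhat(d) for name, d in hyper.items()}
        converged = all(np.isnan(r) or r < settings.rhat_threshold
                        for r in diagnostics.values())
        if not converged:
            worst = max((r, n) for n, r in diagnostics.items() if not np.isnan(r))
            logger.warning("factor %s: possible non-convergence, split R-hat "
                           "%.3f for %s", self.factor, worst[0], worst[1])

        def table(prefix, idx_list):
            rows = {}
            for j in idx_list:
                name = f"{prefix}[{self.items[j]}]"
                d = hyper[name].ravel()
                rows[self.items[j]] = {"mean": d.mean(), "sd": d.std(ddof=1)}
            return pd.DataFrame(rows).T

        def single(name):
            d = hyper[name].ravel()
            return pd.DataFrame({name: {"mean": d.mean(), "sd": d.std(ddof=1)}}).T

        scores = self._df[["group"] + (["id"] if "id" in self._df.columns else [])].copy()
        scores["mean"] = eta_mean
        scores["sd"] = np.sqrt(eta_var)

        if self.random_phi:
            phi_table = pd.concat([single("gamma_phi"), single("sigma_phi")])
        else:
            phi_table = single("phi")

        variance_draws = {}
        for j in self.rand_load:
            variance_draws[("loading", self.items[j])] = \
                hyper[f"sigma_lambda[{self.items[j]}]"].ravel()
        for j in self.rand_uniq:
            variance_draws[("uniqueness", self.items[j])] = \
                hyper[f"sigma_theta[{self.items[j]}]"].ravel()
        if self.random_phi:
            variance_draws[("factor_variance", self.factor)] = hyper["sigma_phi"].ravel()

        pair_cov = {}
        for p in self.pairs:
            total = sum(c["pair_sum"][p] for c in chains) / kept_total
            pair_cov[(self.items[p[0]], self.items[p[1]])] = total

        return MLCFAResults(
            factor=self.factor, items=list(self.items), groups=self.groups,
            settings=settings,
            gamma_lambda=table("gamma_lambda", self.rand_load),
            sigma_lambda=table("sigma_lambda", self.rand_load),
            invariant_loadings=table("lambda", self.inv_load),
            gamma_theta=table("gamma_theta", self.rand_uniq),
            sigma_theta=table("sigma_theta", self.rand_uniq),
            invariant_uniquenesses=table("theta", self.inv_uniq),
            factor_variance=phi_table,
            group_loadings=lam_mean, group_uniquenesses=th_mean,
            group_factor_variances=phi_mean,
            factor_scores=scores, diagnostics=diagnostics, converged=converged,
            residual_covs=pair_cov, _variance_draws=variance_draws,
        )


def fit_mlcfa_block(data: pd.DataFrame, spec: MeasurementSpec, factor: str,
                    settings: MCMCSettings | None = None) -> MLCFAResults:
    """Fit one measurement block (functional wrapper)."""
    return MultilevelCFA(data, spec, factor).fit(settings)


def fit_all_blocks(data: pd.DataFrame, spec: MeasurementSpec,
                   settings: MCMCSettings | None = None) -> list:
    """Fit every factor block on the same rows."""
    return [fit_mlcfa_block(data, spec, f, settings) for f in spec.factors]


def extract_factor_scores(results: list) -> pd.DataFrame:
    """Concatenate per-factor score posteriors into one table.

    Rows of all blocks must align 1:1; the posterior means are re-centered
    per group so the estimated factor scores have exactly zero group means
    (their posterior SDs are unaffected).
    """
    if not results:
        raise ValueError("no block results given")
    base = None
    for res in results:
        sc = res.factor_scores
        cols = sc[["group"] + (["id"] if "id" in sc.columns else [])].reset_index(drop=True)
        if base is None:
            base = cols
            out = cols.copy()
        elif not cols.equals(base):
            raise ValueError("row misalignment between factor blocks")
        out[f"{res.factor}_mean"] = sc["mean"].to_numpy()
        out[f"{res.factor}_sd"] = sc["sd"].to_numpy()
    mean_cols = [f"{r.factor}_mean" for r in results]
    out[mean_cols] = out.groupby("group")[mean_cols].transform(lambda s: s - s.mean())
    return out


def assess_random_effect_variance(result: MLCFAResults, parameter,
                                  threshold: float = 0.01,
                                  level: float = 0.025) -> str:
    """Advisory invariance decision for one random-effect variance.

    ``parameter`` is a ``(kind, name)`` pair, e.g. ``("loading", "y2")``.
    Returns ``"non-invariant"`` when the lower posterior credible bound of
    the variance exceeds ``threshold`` (at quantile ``level``), else
    ``"invariant"``.  The main pipeline takes the invariance pattern as
    given; this check supports exploratory invariance screening.
    """
    key = tuple(parameter)
    if key not in result._variance_draws:
        raise ValueError(
            f"parameter {parameter!r} was not fitted with a random effect")
    draws = result._variance_draws[key]
    lower = float(np.quantile(draws, level))
    return "non-invariant" if lower > threshold else "invariant"
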