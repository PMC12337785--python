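"""Step 3: mixture clustering of groups on their structural relations.

Groups are latent-class members of K clusters.  Conditional on membership,
the latent scores of group g follow MVN(0, Phi_gk) with

    Phi_gk = (I - B_k)^-1 Psi_gk (I - B_k)^-T,

where B_k holds the cluster-specific regression coefficients (recursive
pattern from a :class:`~mixmlsem.specs.StructuralSpec`) and Psi_gk the
residual factor covariances: the exogenous block is free per group, the
endogenous residual variances are free per group, and endogenous residual
covariances are fixed to zero.  Estimation maximizes the covariance-based
mixture log-likelihood over groups (each component density raised to the
group size) by EM with multistart from random hard partitions.

The M-step estimates B_k from the membership-weighted pooled covariance
``sum_g z_gk N_g Phi_g^s2`` — per-equation regression, which is the exact
maximizer for a recursive model with diagonal endogenous residuals fitted
to a single covariance — and then recovers Psi_gk per group as the
structured part of (I - B_k) Phi_g^s2 (I - B_k)^T, flooring negative
endogenous residual variances.  Because Psi_gk is group-specific, the
pooled B-update is not mathematically guaranteed to increase the objective
in heterogeneous configurations; a safeguard therefore rolls a cluster's
update back to its previous B_k whenever the update would lower the
expected complete-data log-likelihood, making the EM sequence monotone by
construction.  Rollbacks are counted in the fit diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .croon import GroupFactorCov, SingleIndicatorParams
from .specs import StructuralSpec

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureParams",
    "GroupMixtureSEM",
    "GroupMixtureResults",
    "EmptyClusterError",
    "e_step",
    "m_step",
    "fit_mixture",
    "hard_partition",
    "observed_loglik",
    "loglik_eta",
]

_PSI_FLOOR = 1e-6
LOG2PI = np.log(2.0 * np.pi)


class EmptyClusterError(RuntimeError):
    """Raised when a cluster loses all its posterior mass (restart signal)."""


@dataclass
class MixtureParams:
    """Mixing proportions, cluster regressions and residual covariances."""

    pi: np.ndarray       # (K,)
    B: np.ndarray        # (K, Q, Q)
    Psi: np.ndarray      # (G, K, Q, Q)

    @property
    def n_clusters(self) -> int:
        return len(self.pi)

    def implied_cov(self) -> np.ndarray:
        """(G, K, Q, Q) model-implied factor covariances Phi_gk."""
        K, Q = self.B.shape[0], self.B.shape[1]
        Minv = np.stack([np.linalg.inv(np.eye(Q) - self.B[k]) for k in range(K)])
        return np.einsum("kab,gkbc,kdc->gkad", Minv, self.Psi, Minv)


def _masks(spec: StructuralSpec):
    exo = np.array([f in spec.exogenous for f in spec.factor_order])
    return np.where(exo)[0], np.where(~exo)[0]


def _endo_residuals(B_k: np.ndarray, S: np.ndarray, endo: np.ndarray) -> np.ndarray:
    """(G, D) endogenous residual variances (M S M')_tt for one cluster."""
    Q = B_k.shape[0]
    M = np.eye(Q) - B_k
    Me = M[endo]                                   # (D, Q)
    return np.einsum("da,gab,db->gd", Me, S, Me)


def _build_psi(B: np.ndarray, S: np.ndarray, exo: np.ndarray, endo: np.ndarray,
               floor: float = _PSI_FLOOR):
    """Structured Psi_gk for every (g, k); returns (Psi, n_floored)."""
    G, Q = S.shape[0], S.shape[1]
    K = B.shape[0]
    psi = np.zeros((G, K, Q, Q))
    n_floored = 0
    psi[:, :, exo[:, None], exo[None, :]] = \
        S[:, exo[:, None], exo[None, :]][:, None]
    for k in range(K):
        d = _endo_residuals(B[k], S, endo)
        n_floored += int(np.sum(d < floor))
        psi[:, k, endo, endo] = np.maximum(d, floor)
    return psi, n_floored


def _component_loglik(params: MixtureParams, covs: GroupFactorCov) -> np.ndarray:
    """(G, K) matrix of N_g-weighted log component densities (no mixing term).

    Generic path for arbitrary parameters; the EM loop uses the structured
    fast path of :class:`GroupMixtureSEM` instead.
    """
    S = covs.phi_s2
    N = np.asarray(covs.n_g, dtype=float)
    Q = S.shape[1]
    phi = params.implied_cov()
    sign, logdet = np.linalg.slogdet(phi)
    if np.any(sign <= 0):
        g, k = np.argwhere(sign <= 0)[0]
        raise np.linalg.LinAlgError(
            f"singular implied covariance for group index {g}, cluster {k}")
    tr = np.einsum("gab,gkba->gk", S, np.linalg.inv(phi))
    return N[:, None] * (-0.5 * (Q * LOG2PI + logdet + tr))


def e_step(params: MixtureParams, covs: GroupFactorCov) -> np.ndarray:
    """Posterior classification probabilities z_gk (log-domain, row-stochastic)."""
    logw = _component_loglik(params, covs) + np.log(params.pi)[None, :]
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def loglik_eta(params: MixtureParams, covs: GroupFactorCov) -> float:
    """The covariance-based mixture log-likelihood maximized by EM."""
    logw = _component_loglik(params, covs) + np.log(params.pi)[None, :]
    return float(logsumexp(logw, axis=1).sum())


def _fit_B_pooled(S_bar: np.ndarray, spec: StructuralSpec) -> np.ndarray:
    """Per-equation regression of each endogenous factor on its predictors."""
    idx = {f: i for i, f in enumerate(spec.factor_order)}
    Q = len(spec.factor_order)
    B = np.zeros((Q, Q))
    preds = {t: [] for t in spec.factor_order}
    for s, t in spec.free_paths:
        preds[t].append(s)
    for t, sources in preds.items():
        if not sources:
            continue
        pi_ = [idx[s] for s in sources]
        ti = idx[t]
        B[ti, pi_] = np.linalg.solve(S_bar[np.ix_(pi_, pi_)], S_bar[pi_, ti])
    return B


def m_step(z: np.ndarray, covs: GroupFactorCov, spec: StructuralSpec,
           min_cluster_mass: float = 1e-8):
    """Update (pi, B_k, Psi_gk) given posterior memberships.

    Raises :class:`EmptyClusterError` when a cluster has (numerically) no
    posterior mass, which the multistart driver treats as a restart signal.
    """
    S = covs.phi_s2
    N = np.asarray(covs.n_g, dtype=float)
    G = S.shape[0]
    K = z.shape[1]
    mass = z.sum(axis=0)
    if np.any(mass < min_cluster_mass):
        k = int(np.argmin(mass))
        raise EmptyClusterError(f"cluster {k} has posterior mass {mass[k]:.3g}")
    pi = mass / G
    exo, endo = _masks(spec)
    w = z * N[:, None]
    B = np.stack([
        _fit_B_pooled(np.einsum("g,gab->ab", w[:, k], S) / w[:, k].sum(), spec)
        for k in range(K)])
    Psi, n_floored = _build_psi(B, S, exo, endo)
    return MixtureParams(pi=pi, B=B, Psi=Psi), {"n_floored": n_floored}


def hard_partition(z: np.ndarray) -> np.ndarray:
    """Modal cluster per group; ties broken toward the lowest cluster index."""
    z = np.asarray(z)
    if z.ndim != 2:
        raise ValueError("z must be a G x K matrix")
    return np.argmax(z, axis=1)


def observed_loglik(params: MixtureParams, scores: pd.DataFrame,
                    si_params: SingleIndicatorParams,
                    ddof: int = 0) -> float:
    """Single-indicator observed-data log-likelihood (for BIC/AIC/CHull).

    Evaluates the mixture density of the estimated factor scores under
    ``Sigma_hat_gk = Lambda_hat_g Phi_gk Lambda_hat_g + Theta_hat_g`` with
    diagonal single-indicator loadings and zero group means (the scores are
    centered per group).  This observed log-likelihood need not increase
    with K because EM maximizes the covariance-based criterion instead.
    """
    from .croon import _group_arrays  # deferred to avoid import cycle

    groups, means, _ = _group_arrays(scores, si_params.factors)
    if not np.array_equal(groups, np.asarray(si_params.groups)):
        raise ValueError("scores and single-indicator parameters disagree on groups")
    Q = len(si_params.factors)
    K = params.n_clusters
    phi = params.implied_cov()
    total = 0.0
    for i in range(len(groups)):
        m = means[i] - means[i].mean(axis=0)
        n = m.shape[0]
        C = m.T @ m / (n - ddof)
        lam, th = si_params.lambda_hat[i], si_params.theta_hat[i]
        terms = np.empty(K)
        for k in range(K):
            sig = lam[:, None] * phi[i, k] * lam[None, :] + np.diag(th)
            sign, logdet = np.linalg.slogdet(sig)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"singular single-indicator covariance for group "
                    f"{groups[i]!r}, cluster {k}")
            tr = np.trace(np.linalg.solve(sig, C))
            terms[k] = np.log(params.pi[k]) - 0.5 * n * (Q * LOG2PI + logdet + tr)
        total += logsumexp(terms)
    return float(total)


@dataclass
class GroupMixtureResults:
    """Fitted mixture: parameters, memberships and diagnostics."""

    model: "GroupMixtureSEM"
    params: MixtureParams
    z: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    start_id: int
    start_logliks: np.ndarray
    n_floored: int = 0
    n_rollback: int = 0
    n_restarts: int = 0
    loglik_obs: float | None = None

    @property
    def n_clusters(self) -> int:
        return self.params.n_clusters

    def hard_partition(self) -> np.ndarray:
        return hard_partition(self.z)

    def classification_uncertainty(self) -> float:
        """Mean of 1 - max_k z_gk across groups."""
        return float(np.mean(1.0 - self.z.max(axis=1)))

    def observed_loglik(self, scores: pd.DataFrame,
                        si_params: SingleIndicatorParams, ddof: int = 0) -> float:
        self.loglik_obs = observed_loglik(self.params, scores, si_params, ddof=ddof)
        return self.loglik_obs

    def beta_frame(self) -> pd.DataFrame:
        spec = self.model.spec
        idx = {f: i for i, f in enumerate(spec.factor_order)}
        rows = []
        for k in range(self.n_clusters):
            row = {"cluster": k + 1, "pi": self.params.pi[k]}
            for s, t in spec.free_paths:
                row[f"{s}->{t}"] = self.params.B[k, idx[t], idx[s]]
            rows.append(row)
        return pd.DataFrame(rows).set_index("cluster")

    def summary(self) -> str:
        lines = [
            "Group mixture SEM (structural step)",
            "=" * 46,
            f"groups: {self.model.covs.n_groups}    clusters: {self.n_clusters}",
            f"logL (covariance criterion): {self.loglik:.4f}",
            f"converged: {self.converged} in {self.n_iter} iterations "
            f"(best of {len(self.start_logliks)} starts, start {self.start_id})",
            f"classification uncertainty: {self.classification_uncertainty():.4f}",
            "",
            self.beta_frame().round(4).to_string(),
        ]
        if self.n_floored or self.n_rollback or self.n_restarts:
            lines.append("")
            lines.append(
                f"diagnostics: {self.n_floored} floored residual variances, "
                f"{self.n_rollback} safeguarded B-updates, "
                f"{self.n_restarts} empty-cluster restarts")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "pi": self.params.pi.tolist(),
            "B": self.params.B.tolist(),
            "z": self.z.tolist(),
            "loglik": self.loglik,
            "loglik_obs": self.loglik_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "start_id": self.start_id,
        }


class GroupMixtureSEM:
    """Mixture-of-groups structural model on Croon-corrected covariances.

    Parameters
    ----------
    covs : GroupFactorCov
        Per-group corrected factor covariance matrices with group sizes.
    spec : StructuralSpec
        Recursive regression pattern.
    """

    def __init__(self, covs: GroupFactorCov, spec: StructuralSpec):
        if list(covs.factors) != list(spec.factor_order):
            raise ValueError("covariance factors and structural spec disagree")
        self.covs = covs
        self.spec = spec
        self._exo, self._endo = _masks(spec)
        S = covs.phi_s2
        self._N = np.asarray(covs.n_g, dtype=float)
        exo = self._exo
        S_exo = S[:, exo[:, None], exo[None, :]]
        sign, self._logdet_exo = np.linalg.slogdet(S_exo)
        if np.any(sign <= 0):
            raise ValueError("exogenous block of a corrected covariance is "
                             "not positive definite")

    # -- fast structured component log-likelihoods ------------------------
    def _cluster_ll(self, B: np.ndarray) -> np.ndarray:
        """(G, K) N_g-weighted log densities with Psi_gk implicitly recomputed.

        With the structured Psi, |Phi_gk| = |S_g,exo| * prod_t psi_tgk and
        tr(S_g Phi_gk^-1) = |exo| + sum_t d_tgk / psi_tgk where d are the
        endogenous residual variances (M S M')_tt and psi their floored
        values, so no matrix inversions are needed.
        """
        S = self.covs.phi_s2
        Q = S.shape[1]
        K = B.shape[0]
        n_exo = len(self._exo)
        G = S.shape[0]
        ll = np.empty((G, K))
        for k in range(K):
            d = _endo_residuals(B[k], S, self._endo)        # (G, D)
            dc = np.maximum(d, _PSI_FLOOR)
            logdet = self._logdet_exo + np.log(dc).sum(axis=1)
            tr = n_exo + (d / dc).sum(axis=1)
            ll[:, k] = -0.5 * self._N * (Q * LOG2PI + logdet + tr)
        return ll

    def _m_step_fast(self, z: np.ndarray):
        """(pi, B) update without materializing Psi."""
        S = self.covs.phi_s2
        G, K = z.shape
        mass = z.sum(axis=0)
        if np.any(mass < 1e-8):
            k = int(np.argmin(mass))
            raise EmptyClusterError(f"cluster {k} has posterior mass {mass[k]:.3g}")
        pi = mass / G
        w = z * self._N[:, None]
        B = np.stack([
            _fit_B_pooled(np.einsum("g,gab->ab", w[:, k], S) / w[:, k].sum(),
                          self.spec)
            for k in range(K)])
        return pi, B

    def _run_em(self, z0: np.ndarray, tol: float, max_iter: int):
        pi, B = self._m_step_fast(z0)
        llmat = self._cluster_ll(B)
        ll = float(logsumexp(llmat + np.log(pi)[None, :], axis=1).sum())
        converged = False
        n_rollback = 0
        it = 0
        for it in range(1, max_iter + 1):
            logw = llmat + np.log(pi)[None, :]
            z = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
            pi_new, B_new = self._m_step_fast(z)
            llmat_new = self._cluster_ll(B_new)
            ll_new = float(logsumexp(llmat_new + np.log(pi_new)[None, :], axis=1).sum())
            if ll_new < ll:
                # roll back cluster updates that lower the expected
                # complete-data log-likelihood (see module docstring)
                for k in range(B.shape[0]):
                    if (z[:, k] * llmat_new[:, k]).sum() < (z[:, k] * llmat[:, k]).sum():
                        B_new[k] = B[k]
                        n_rollback += 1
                llmat_new = self._cluster_ll(B_new)
                ll_new = float(logsumexp(llmat_new + np.log(pi_new)[None, :],
                                         axis=1).sum())
            if ll_new < ll - 1e-6 * max(1.0, abs(ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({ll:.8f} -> {ll_new:.8f})")
            delta = ll_new - ll
            pi, B, llmat, ll = pi_new, B_new, llmat_new, ll_new
            if abs(delta) < tol:
                converged = True
                break
        logw = llmat + np.log(pi)[None, :]
        z = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        Psi, n_floored = _build_psi(B, self.covs.phi_s2, self._exo, self._endo)
        params = MixtureParams(pi=pi, B=B, Psi=Psi)
        return params, z, ll, it, converged, n_floored, n_rollback

    def fit(self, n_clusters: int, n_starts: int = 50, tol: float = 1e-6,
            max_iter: int = 500, seed: int = 0,
            initial_partition: np.ndarray | None = None) -> GroupMixtureResults:
        """EM with multistart from random hard partitions.

        Each start assigns every group uniformly at random to a cluster
        (seeded; up to 3 redraws on degenerate or emptied partitions); the
        start with the highest final log-likelihood wins.
        ``initial_partition`` replaces the random starts by a single start
        from the given hard clustering (used for the global-optimum proxy).
        """
        G = self.covs.n_groups
        K = int(n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if G < K:
            raise ValueError("need at least as many groups as clusters")

        if initial_partition is not None:
            part = np.asarray(initial_partition, dtype=int)
            if part.shape != (G,):
                raise ValueError("initial_partition must have one entry per group")
            starts = [part]
        elif K == 1:
            starts = [np.zeros(G, dtype=int)]
        else:
            starts = [None] * n_starts

        best = None
        start_logliks = np.full(len(starts), -np.inf)
        failures = []
        total_restarts = 0
        for sid, part in enumerate(starts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 101, sid]))
            out = None
            for attempt in range(4):
                cand = part if (part is not None and attempt == 0) \
                    else rng.integers(0, K, size=G)
                if K > 1 and len(np.unique(cand)) < K:
                    continue
                z0 = np.zeros((G, K))
                z0[np.arange(G), cand] = 1.0
                try:
                    out = self._run_em(z0, tol, max_iter)
                    break
                except EmptyClusterError as err:
                    total_restarts += 1
                    logger.info("start %d: %s; redrawing partition", sid, err)
            if out is None:
                failures.append(sid)
                continue
            params, z, ll, it, conv, nfl, nrb = out
            start_logliks[sid] = ll
            if best is None or ll > best.loglik:
                best = GroupMixtureResults(
                    model=self, params=params, z=z, loglik=ll, n_iter=it,
                    converged=conv, start_id=sid, start_logliks=start_logliks,
                    n_floored=nfl, n_rollback=nrb)
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} starts failed (start ids: {failures})")
        best.start_logliks = start_logliks
        best.n_restarts = total_restarts
        return best


def fit_mixture(covs: GroupFactorCov, spec: StructuralSpec, n_clusters: int,
                n_starts: int = 50, tol: float = 1e-6, max_iter: int = 500,
                seed: int = 0) -> GroupMixtureResults:
    """Functional wrapper around :meth:`GroupMixtureSEM.fit`."""
    return GroupMixtureSEM(covs, spec).fit(
        n_clusters, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed)
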