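"""Step 2: factor scores -> group-specific, bias-corrected factor covariances.

The posterior-mean factor scores from Step 1 act as a single observed
indicator per factor.  Their reliability in group g,
``lambda_qg = var(E(f_qng)) / phi_qg`` with total factor variance
``phi_qg = var(E(f_qng)) + E(var(f_qng))``, defines a per-group diagonal
loading matrix; the single-indicator unique variance is
``phi_qg * lambda_qg * (1 - lambda_qg)``.  Croon's correction then removes
the attenuation incurred by using scores instead of true latent variables:

    Phi_g^s2 = Lambda_g^-1 (cov(F_g) - Theta_g) Lambda_g^-T

These corrected covariance matrices (plus group sizes) are the complete
interface to the mixture clustering of Step 3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SingleIndicatorParams",
    "GroupFactorCov",
    "single_indicator_params",
    "croon_corrected_cov",
]


def score_columns(factors) -> list:
    cols = []
    for f in factors:
        cols += [f"{f}_mean", f"{f}_sd"]
    return cols


@dataclass
class SingleIndicatorParams:
    """Per-group single-indicator measurement parameters (diagonal)."""

    groups: np.ndarray         # (G,) group labels
    factors: list              # Q factor names
    lambda_hat: np.ndarray     # (G, Q) reliabilities
    theta_hat: np.ndarray      # (G, Q) single-indicator unique variances
    phi_hat: np.ndarray        # (G, Q) total factor variances

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups):
            for q, f in enumerate(self.factors):
                rows.append({"group": g, "factor": f,
                             "lambda": self.lambda_hat[i, q],
                             "theta": self.theta_hat[i, q],
                             "phi": self.phi_hat[i, q]})
        return pd.DataFrame(rows)


@dataclass
class GroupFactorCov:
    """Croon-corrected factor covariance matrices, the Step-3 input."""

    groups: np.ndarray         # (G,)
    factors: list
    phi_s2: np.ndarray         # (G, Q, Q) corrected covariances
    cov_F: np.ndarray          # (G, Q, Q) raw factor-score covariances
    n_g: np.ndarray            # (G,) group sizes
    repaired: list = field(default_factory=list)   # groups needing a PD repair

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def to_json(self, path) -> None:
        payload = {
            "groups": np.asarray(self.groups).tolist(),
            "factors": list(self.factors),
            "phi_s2": self.phi_s2.tolist(),
            "cov_F": self.cov_F.tolist(),
            "n_g": np.asarray(self.n_g).tolist(),
            "repaired": list(self.repaired),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroupFactorCov":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            groups=np.asarray(d["groups"]),
            factors=list(d["factors"]),
            phi_s2=np.asarray(d["phi_s2"], dtype=float),
            cov_F=np.asarray(d["cov_F"], dtype=float),
            n_g=np.asarray(d["n_g"], dtype=int),
            repaired=list(d.get("repaired", [])),
        )


def _group_arrays(scores: pd.DataFrame, factors):
    """Split the score table into per-group (E(f), sd(f)) arrays."""
    mean_cols = [f"{f}_mean" for f in factors]
    sd_cols = [f"{f}_sd" for f in factors]
    missing = [c for c in mean_cols + sd_cols if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    groups, means, sds = [], [], []
    for g, sub in scores.groupby("group", sort=True):
        groups.append(g)
        means.append(sub[mean_cols].to_numpy(dtype=float))
        sds.append(sub[sd_cols].to_numpy(dtype=float))
    return np.asarray(groups), means, sds


def single_indicator_params(
    scores: pd.DataFrame,
    factors,
    external_phi: np.ndarray | None = None,
    ddof: int = 0,
) -> SingleIndicatorParams:
    """Derive per-group reliabilities and single-indicator parameters.

    ``scores`` holds one row per individual with columns ``group`` and
    ``{factor}_mean`` / ``{factor}_sd``.  Scores are centered per group
    before variances are taken (centering does not affect them).  ``ddof=0``
    matches the population covariance convention of the fixed-sample
    generator.  ``external_phi`` replaces the score-based total factor
    variance; it can push the reliability above one, which is rejected.
    """
    groups, means, sds = _group_arrays(scores, factors)
    G, Q = len(groups), len(factors)
    lam = np.empty((G, Q))
    phi = np.empty((G, Q))
    for i in range(G):
        m = means[i] - means[i].mean(axis=0)
        n = m.shape[0]
        if n < 2:
            raise ValueError(f"group {groups[i]!r} has fewer than 2 rows")
        var_E = m.var(axis=0, ddof=ddof)
        if np.any(var_E <= 0):
            bad = [factors[q] for q in np.where(var_E <= 0)[0]]
            raise ValueError(
                f"group {groups[i]!r}: zero variance of the estimated factor "
                f"scores for {bad}; degenerate factor")
        E_var = (sds[i] ** 2).mean(axis=0)
        if external_phi is None:
            phi[i] = var_E + E_var
        else:
            phi[i] = np.asarray(external_phi)[i]
        lam[i] = var_E / phi[i]
        if np.any(lam[i] > 1.0 + 1e-12):
            raise ValueError(
                f"group {groups[i]!r}: reliability exceeds one "
                "(externally supplied factor variance is smaller than the "
                "score variance, implying a negative unique variance)")
    lam = np.minimum(lam, 1.0)
    theta = phi * lam * (1.0 - lam)
    return SingleIndicatorParams(groups=groups, factors=list(factors),
                                 lambda_hat=lam, theta_hat=theta, phi_hat=phi)


def _repair_pd(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping with re-symmetrization."""
    sym = (mat + mat.T) / 2.0
    w, V = np.linalg.eigh(sym)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def croon_corrected_cov(
    scores: pd.DataFrame,
    params: SingleIndicatorParams,
    ddof: int = 0,
    pd_floor: float = 1e-6,
) -> GroupFactorCov:
    """Apply Croon's correction per group.

    With diagonal ``Lambda_hat`` the correction is elementwise:
    ``Phi[q, r] = (cov(F)[q, r] - theta[q]·1{q=r}) / (lambda[q] lambda[r])``.
    Non-positive-definite results are repaired by eigenvalue clipping (the
    mixture step requires invertible input) and the repair is logged.
    """
    groups, means, _ = _group_arrays(scores, params.factors)
    if not np.array_equal(groups, np.asarray(params.groups)):
        raise ValueError("params were computed for a different set of groups")
    G, Q = len(groups), len(params.factors)
    phi_s2 = np.empty((G, Q, Q))
    cov_F = np.empty((G, Q, Q))
    n_g = np.empty(G, dtype=int)
    repaired = []
    for i in range(G):
        m = means[i] - means[i].mean(axis=0)
        n = m.shape[0]
        n_g[i] = n
        C = m.T @ m / (n - ddof)
        cov_F[i] = C
        lam = params.lambda_hat[i]
        if np.any(lam <= 0):
            raise ValueError(f"group {groups[i]!r}: singular single-indicator loading matrix")
        corrected = (C - np.diag(params.theta_hat[i])) / np.outer(lam, lam)
        corrected = (corrected + corrected.T) / 2.0
        if np.linalg.eigvalsh(corrected)[0] <= 0:
            corrected = _repair_pd(corrected, pd_floor)
            repaired.append(groups[i].item() if hasattr(groups[i], "item") else groups[i])
            logger.warning("group %r: corrected factor covariance repaired to PD", groups[i])
        phi_s2[i] = corrected
    return GroupFactorCov(groups=groups, factors=list(params.factors),
                          phi_s2=phi_s2, cov_F=cov_F, n_g=n_g, repaired=repaired)
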