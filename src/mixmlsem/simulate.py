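"""Synthetic multigroup SEM data following the simulation-study design.

The generator produces item scores for G groups nested in K clusters of
equal size.  Four factors are each measured by five items; clusters differ
only in the regression relations among the factors (one of the four
coefficients is zeroed per cluster), while measurement parameters vary
across groups: the second and third item of every factor have normally
distributed random loadings and log-normally distributed random unique
variances, and every group has its own exogenous factor covariance (Wishart)
and endogenous total variances (log-normal).

Within-group samples are either ``fixed`` (the empirical item covariance of
each group exactly equals the model-implied covariance, emulating exhaustive
sampling of a group) or ``random`` (i.i.d. multivariate normal rows).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .specs import MeasurementSpec, StructuralSpec, BETA_PATHS

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "build_cluster_regressions",
    "sample_group_structure",
    "generate_group_parameters",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

N_FACTORS = 4
ITEMS_PER_FACTOR = 5
N_ITEMS = N_FACTORS * ITEMS_PER_FACTOR

# Invariant measurement parameter values per reliability level.
INVARIANT_LOADING = {"high": 0.6, "low": 0.4}
INVARIANT_UNIQUENESS = {"high": 0.4, "low": 0.6}
# Random loadings: Normal(mean, variance 0.1); random unique variances:
# log-normal with log-SD 0.25 and log-mean chosen to center near 0.4 / 0.6.
RANDOM_LOADING_VAR = 0.1
UNIQ_LOG_MEAN = {"high": -0.948, "low": -0.542}
UNIQ_LOG_SD = 0.25


@dataclass
class SimulationDesign:
    """One cell of the simulation-study factorial design.

    The defaults for the Wishart dispersion (``wishart_df``/``wishart_mean``)
    reproduce the realized moments of the exogenous factor (co)variances in
    the study design: Var(F1)_g and Var(F2)_g with mean 0.952 and SD 0.166,
    Cov(F1, F2)_g with mean 0 and SD 0.117.  ``endo_log_sd`` is the log-scale
    SD of the endogenous total variances (log-mean fixed at 0).
    """

    n_groups: int = 48
    n_clusters: int = 2
    small_n: int = 25
    large_n: int = 100
    small_prop: float = 0.5
    beta: float = 0.3
    reliability: str = "high"
    sampling: str = "fixed"
    seed: int = 0
    wishart_df: int = 66
    wishart_mean: float = 0.952
    endo_log_sd: float = 0.25
    strict: bool = True

    def __post_init__(self):
        if self.strict and self.n_clusters not in (2, 4):
            raise ValueError("n_clusters must be 2 or 4 in the study design (strict mode)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_groups % self.n_clusters != 0:
            raise ValueError("n_clusters must divide n_groups (balanced clusters)")
        if not 0.0 <= self.small_prop <= 1.0:
            raise ValueError("small_prop must lie in [0, 1]")
        if self.reliability not in ("high", "low"):
            raise ValueError("reliability must be 'high' or 'low'")
        if self.sampling not in ("fixed", "random"):
            raise ValueError("sampling must be 'fixed' or 'random'")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        return cls(**d)


@dataclass
class GroundTruth:
    """True parameters and clustering behind a generated dataset.

    Arrays are indexed by group g (0..G-1), factor q (0..3) and item j
    (0..4 within the factor).  ``B_true`` holds one 4x4 regression matrix per
    cluster (strictly lower triangular in the order F1..F4); ``Psi_true`` the
    structured residual covariance (free exogenous block, endogenous residual
    variances on the diagonal); ``Phi_true`` the implied factor covariance
    and ``Sigma_true`` the implied item covariance of each group.
    """

    cluster_of_group: np.ndarray          # (G,)
    group_sizes: np.ndarray               # (G,)
    B_true: np.ndarray                    # (K, 4, 4)
    Lambda_true: np.ndarray               # (G, 4, 5)
    Theta_true: np.ndarray                # (G, 4, 5)
    Psi_true: np.ndarray                  # (G, 4, 4)
    Phi_true: np.ndarray                  # (G, 4, 4)
    Sigma_true: np.ndarray                # (G, 20, 20)
    design: SimulationDesign | None = None
    resample_events: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.cluster_of_group)

    @property
    def n_clusters(self) -> int:
        return len(self.B_true)

    def beta_table(self) -> pd.DataFrame:
        """Cluster-specific coefficients under the canonical labels."""
        spec = StructuralSpec.four_factor_default()
        idx = {f: i for i, f in enumerate(spec.factor_order)}
        rows = {}
        for label, (s, t) in BETA_PATHS.items():
            rows[label] = self.B_true[:, idx[t], idx[s]]
        return pd.DataFrame(rows, index=[f"cluster{k + 1}" for k in range(self.n_clusters)])

    def noninvariant_loadings(self) -> np.ndarray:
        """(G, 4, 2) array of the group-specific loadings of items 2-3."""
        return self.Lambda_true[:, :, 1:3]

    def noninvariant_uniquenesses(self) -> np.ndarray:
        return self.Theta_true[:, :, 1:3]

    def to_json(self, path) -> None:
        payload = {
            "cluster_of_group": self.cluster_of_group.tolist(),
            "group_sizes": self.group_sizes.tolist(),
            "B_true": self.B_true.tolist(),
            "Lambda_true": self.Lambda_true.tolist(),
            "Theta_true": self.Theta_true.tolist(),
            "Psi_true": self.Psi_true.tolist(),
            "Phi_true": self.Phi_true.tolist(),
            "Sigma_true": self.Sigma_true.tolist(),
            "design": self.design.to_dict() if self.design is not None else None,
            "resample_events": self.resample_events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        design = SimulationDesign.from_dict(d["design"]) if d.get("design") else None
        return cls(
            cluster_of_group=np.asarray(d["cluster_of_group"], dtype=int),
            group_sizes=np.asarray(d["group_sizes"], dtype=int),
            B_true=np.asarray(d["B_true"], dtype=float),
            Lambda_true=np.asarray(d["Lambda_true"], dtype=float),
            Theta_true=np.asarray(d["Theta_true"], dtype=float),
            Psi_true=np.asarray(d["Psi_true"], dtype=float),
            Phi_true=np.asarray(d["Phi_true"], dtype=float),
            Sigma_true=np.asarray(d["Sigma_true"], dtype=float),
            design=design,
            resample_events=int(d.get("resample_events", 0)),
        )


def build_cluster_regressions(n_clusters: int, beta: float, strict: bool = True) -> np.ndarray:
    """Cluster-specific 4x4 regression matrices.

    Cluster k (1-based) zeroes coefficient beta_k and sets the other three of
    beta1..beta4 equal to ``beta``; with beta1: F1->F4, beta2: F1->F3,
    beta3: F2->F3, beta4: F3->F4.  Each pair of clusters therefore differs
    in exactly two coefficients, each by magnitude ``beta``.
    """
    if strict and n_clusters not in (2, 4):
        raise ValueError("n_clusters must be 2 or 4 in the study design (strict mode)")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    spec = StructuralSpec.four_factor_default()
    idx = {f: i for i, f in enumerate(spec.factor_order)}
    labels = ["beta1", "beta2", "beta3", "beta4"]
    B = np.zeros((n_clusters, 4, 4))
    for k in range(n_clusters):
        zeroed = labels[k % 4]
        for label in labels:
            s, t = BETA_PATHS[label]
            B[k, idx[t], idx[s]] = 0.0 if label == zeroed else beta
    return B


def sample_group_structure(design: SimulationDesign, rng: np.random.Generator | None = None):
    """Balanced cluster assignment and group sizes.

    Each cluster receives G/K groups; within each cluster,
    ``round(small_prop * G/K)`` randomly chosen groups get ``small_n`` rows
    and the rest ``large_n``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    G, K = design.n_groups, design.n_clusters
    per = G // K
    cluster_of_group = np.repeat(np.arange(K), per)
    sizes = np.empty(G, dtype=int)
    n_small = int(round(design.small_prop * per))
    for k in range(K):
        members = np.where(cluster_of_group == k)[0]
        small = rng.choice(members, size=n_small, replace=False)
        sizes[members] = design.large_n
        sizes[small] = design.small_n
    return sizes, cluster_of_group


def _draw_exogenous_block(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """2x2 Wishart draw for the (F1, F2) residual covariance.

    W ~ Wishart(df, (m/df) I) has mean m·I, Var(W_ii) = 2 m^2/df and
    Var(W_12) = m^2/df, reproducing the target dispersion of the design.
    """
    df, m = design.wishart_df, design.wishart_mean
    scale_chol = np.sqrt(m / df)
    # Bartlett decomposition, 2x2
    c11 = np.sqrt(rng.chisquare(df))
    c22 = np.sqrt(rng.chisquare(df - 1))
    n21 = rng.standard_normal()
    A = np.array([[c11, 0.0], [n21, c22]])
    L = scale_chol * A
    return L @ L.T


def generate_group_parameters(
    design: SimulationDesign,
    cluster_of_group: np.ndarray,
    group_sizes: np.ndarray,
    rng: np.random.Generator | None = None,
    max_resample: int = 100,
) -> GroundTruth:
    """Draw all group-level parameters and assemble the implied covariances."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, 13]))
    G = design.n_groups
    B = build_cluster_regressions(design.n_clusters, design.beta, strict=design.strict)
    rel = design.reliability
    lam_inv = INVARIANT_LOADING[rel]
    th_inv = INVARIANT_UNIQUENESS[rel]

    Lambda = np.empty((G, N_FACTORS, ITEMS_PER_FACTOR))
    Theta = np.empty((G, N_FACTORS, ITEMS_PER_FACTOR))
    Psi = np.zeros((G, N_FACTORS, N_FACTORS))
    Phi = np.empty((G, N_FACTORS, N_FACTORS))
    Sigma = np.empty((G, N_ITEMS, N_ITEMS))
    resample_events = 0

    spec = StructuralSpec.four_factor_default()
    idx = {f: i for i, f in enumerate(spec.factor_order)}
    i1, i2, i3, i4 = (idx[f] for f in ("F1", "F2", "F3", "F4"))

    for g in range(G):
        k = cluster_of_group[g]
        Bk = B[k]
        b2 = Bk[i3, i1]  # F1 -> F3
        b3 = Bk[i3, i2]  # F2 -> F3
        b1 = Bk[i4, i1]  # F1 -> F4
        b4 = Bk[i4, i3]  # F3 -> F4

        exo = _draw_exogenous_block(design, rng)
        v1, v2, c12 = exo[0, 0], exo[1, 1], exo[0, 1]

        psi3 = psi4 = -1.0
        attempts = 0
        while (psi3 <= 0 or psi4 <= 0):
            if attempts >= max_resample:
                raise RuntimeError(
                    f"group {g}: could not draw positive endogenous residual "
                    f"variances after {max_resample} attempts"
                )
            v3, v4 = np.exp(rng.normal(0.0, design.endo_log_sd, size=2))
            psi3 = v3 - (b2 ** 2 * v1 + b3 ** 2 * v2 + 2 * b2 * b3 * c12)
            psi4 = v4 - (b1 ** 2 * v1 + b4 ** 2 * v3
                         + 2 * b1 * b4 * (b2 * v1 + b3 * c12))
            attempts += 1
        if attempts > 1:
            resample_events += attempts - 1
            logger.info("group %d: resampled endogenous totals %d time(s)", g, attempts - 1)

        Psi[g, i1, i1], Psi[g, i2, i2] = v1, v2
        Psi[g, i1, i2] = Psi[g, i2, i1] = c12
        Psi[g, i3, i3], Psi[g, i4, i4] = psi3, psi4

        M = np.eye(N_FACTORS) - Bk
        Minv = np.linalg.inv(M)
        Phi[g] = Minv @ Psi[g] @ Minv.T

        lam = np.empty((N_FACTORS, ITEMS_PER_FACTOR))
        th = np.empty((N_FACTORS, ITEMS_PER_FACTOR))
        lam[:, 0] = 1.0                                   # marker items
        lam[:, 1:3] = rng.normal(lam_inv, np.sqrt(RANDOM_LOADING_VAR), size=(N_FACTORS, 2))
        lam[:, 3:] = lam_inv
        th[:, 0] = th_inv
        th[:, 1:3] = np.exp(rng.normal(UNIQ_LOG_MEAN[rel], UNIQ_LOG_SD, size=(N_FACTORS, 2)))
        th[:, 3:] = th_inv
        Lambda[g], Theta[g] = lam, th

        # 20x4 loading matrix: item j of factor q in row 5q+j
        Lmat = np.zeros((N_ITEMS, N_FACTORS))
        for q in range(N_FACTORS):
            Lmat[5 * q:5 * (q + 1), q] = lam[q]
        Sigma[g] = Lmat @ Phi[g] @ Lmat.T + np.diag(th.ravel())

    return GroundTruth(
        cluster_of_group=np.asarray(cluster_of_group, dtype=int),
        group_sizes=np.asarray(group_sizes, dtype=int),
        B_true=B, Lambda_true=Lambda, Theta_true=Theta,
        Psi_true=Psi, Phi_true=Phi, Sigma_true=Sigma,
        design=design, resample_events=resample_events,
    )


def _fixed_sample(n: int, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample whose empirical covariance (denominator n) equals ``sigma``.

    A raw normal sample is centered, whitened with the Cholesky factor of its
    own empirical covariance and recolored with that of ``sigma``.
    """
    p = sigma.shape[0]
    if n < p + 1:
        raise ValueError(
            f"fixed sampling needs at least {p + 1} rows per group (got {n}): "
            "the empirical covariance would be singular"
        )
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    S = X.T @ X / n
    L0 = np.linalg.cholesky(S)
    L1 = np.linalg.cholesky(sigma)
    return X @ np.linalg.inv(L0).T @ L1.T


def generate_dataset(design: SimulationDesign):
    """Generate one dataset: returns ``(DataFrame, GroundTruth)``.

    The frame has columns ``group`` (1-based), ``id`` and ``y1..y20``.  One
    seed governs the whole dataset; per-group sampling uses spawned
    independent streams so generation is reproducible.
    """
    root = np.random.SeedSequence([int(design.seed), 7])
    ss_structure, ss_params, ss_data = root.spawn(3)
    sizes, cluster_of_group = sample_group_structure(
        design, np.random.default_rng(ss_structure))
    truth = generate_group_parameters(
        design, cluster_of_group, sizes, np.random.default_rng(ss_params))

    group_streams = ss_data.spawn(design.n_groups)
    frames = []
    for g in range(design.n_groups):
        rng = np.random.default_rng(group_streams[g])
        n = int(sizes[g])
        if design.sampling == "fixed":
            X = _fixed_sample(n, truth.Sigma_true[g], rng)
        else:
            X = rng.multivariate_normal(
                np.zeros(N_ITEMS), truth.Sigma_true[g], size=n, method="cholesky")
        df = pd.DataFrame(X, columns=[f"y{j + 1}" for j in range(N_ITEMS)])
        df.insert(0, "id", np.arange(1, n + 1))
        df.insert(0, "group", g + 1)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return data, truth


def write_dataset(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
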