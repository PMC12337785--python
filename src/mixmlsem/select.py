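"""Choosing the number of clusters: BIC, AIC and the CHull scree test.

The information criteria use the single-indicator observed log-likelihood
(see :func:`mixmlsem.mixture.observed_loglik`).  ``BIC_G`` takes the sample
size to be the number of groups G — the variant that performs best for
group-level mixtures — while ``BIC_N`` (total observations) is available as
a secondary variant.  The CHull procedure selects the model with the
highest scree ratio on the upper convex hull of (complexity, fit) points;
it can never select the least complex model, and an (effectively) zero
denominator yields an infinite ratio, which is flagged so the second-best
ratio can be consulted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .specs import StructuralSpec

__all__ = [
    "count_free_params",
    "bic",
    "bic_g",
    "aic",
    "ChullReport",
    "chull_select",
    "selection_table",
    "select_n_clusters",
    "plot_chull",
]


def n_psi_cells(spec: StructuralSpec) -> int:
    """Free residual (co)variance cells per group: full exogenous block plus
    one residual variance per endogenous factor."""
    e = len(spec.exogenous)
    d = spec.n_factors - e
    return e * (e + 1) // 2 + d


def count_free_params(n_clusters: int, n_groups: int, spec: StructuralSpec,
                      n_factors: int | None = None,
                      n_psi: int | None = None) -> int:
    """Free-parameter count P for the mixture model with K clusters.

    P = (K-1) mixing proportions + K * |free paths| + G * |free Psi cells|
    (one set per group: the model assigns each group to a single cluster)
    + 2*Q*G single-indicator measurement parameters (a loading and a unique
    variance per group and factor).
    """
    Q = spec.n_factors if n_factors is None else n_factors
    npsi = n_psi_cells(spec) if n_psi is None else n_psi
    return ((n_clusters - 1) + n_clusters * len(spec.free_paths)
            + n_groups * npsi + 2 * Q * n_groups)


def bic(loglik: float, n_params: int, sample_size: float) -> float:
    return -2.0 * loglik + n_params * np.log(sample_size)


def bic_g(loglik: float, n_params: int, n_groups: int) -> float:
    """BIC with the number of groups as the sample size."""
    return bic(loglik, n_params, n_groups)


def aic(loglik: float, n_params: int) -> float:
    return -2.0 * loglik + 2.0 * n_params


@dataclass
class ChullReport:
    """Outcome of the generalized scree test."""

    selected: object = None          # K with the highest scree ratio (None if no solution)
    best_ratio: float = np.nan
    second: object = None            # K with the second-highest ratio
    second_ratio: float = np.nan
    ratios: dict = field(default_factory=dict)   # K -> scree ratio (interior hull points)
    hull: list = field(default_factory=list)     # K values on the upper convex hull
    excluded: list = field(default_factory=list) # K values dropped (dominated / non-monotone)
    infinite_ratio: bool = False
    nonmonotone_loglik: bool = False
    no_solution: bool = False
    tie: bool = False


def chull_select(n_params: np.ndarray, logliks: np.ndarray,
                 labels: np.ndarray | None = None) -> ChullReport:
    """Generalized scree test on (P, logL) points.

    Models are sorted by complexity; dominated models (fit not better than a
    simpler model) are excluded, the upper convex hull is formed, and the
    scree ratio of each interior hull model i is

        [(logL_i - logL_{i-1}) / (P_i - P_{i-1})]
            / [(logL_{i+1} - logL_i) / (P_{i+1} - P_i)].

    The model with the highest ratio is selected; ties break toward the
    simpler model.  Endpoints have no ratio, so the least complex model can
    never be selected.
    """
    P = np.asarray(n_params, dtype=float)
    L = np.asarray(logliks, dtype=float)
    if labels is None:
        labels = np.arange(1, len(P) + 1)
    labels = np.asarray(labels)
    if len(set(P.tolist())) != len(P):
        raise ValueError("models must have distinct parameter counts")
    order = np.argsort(P)
    P, L, labels = P[order], L[order], labels[order]

    report = ChullReport()
    report.nonmonotone_loglik = bool(np.any(np.diff(L) < 0))

    # drop models with strictly worse fit than a simpler model; equal-fit
    # models are kept, so a zero fit gain yields an infinite scree ratio at
    # the preceding model rather than silently shrinking the hull.  Fits
    # within floating-point noise of the running best are snapped to it.
    tol = 1e-9 * max(1.0, np.abs(L).max())
    keep = []
    best = -np.inf
    for i in range(len(P)):
        if L[i] >= best - tol:
            keep.append(i)
            if L[i] < best:
                L[i] = best
            best = L[i]
        else:
            report.excluded.append(labels[i].item() if hasattr(labels[i], "item")
                                   else labels[i])
    idx = list(keep)

    # upper convex hull by repeated removal of concave-violating middles
    changed = True
    while changed and len(idx) >= 3:
        changed = False
        for j in range(1, len(idx) - 1):
            a, b, c = idx[j - 1], idx[j], idx[j + 1]
            left = (L[b] - L[a]) / (P[b] - P[a])
            right = (L[c] - L[b]) / (P[c] - P[b])
            if left < right:  # collinear points stay (they carry ratio ties)
                report.excluded.append(labels[b].item() if hasattr(labels[b], "item")
                                       else labels[b])
                del idx[j]
                changed = True
                break
    report.hull = [labels[i].item() if hasattr(labels[i], "item") else labels[i]
                   for i in idx]

    if len(idx) < 3:
        report.no_solution = True
        return report

    ratios = {}
    for j in range(1, len(idx) - 1):
        a, b, c = idx[j - 1], idx[j], idx[j + 1]
        num = (L[b] - L[a]) / (P[b] - P[a])
        den = (L[c] - L[b]) / (P[c] - P[b])
        if den <= 0:
            if num <= 0:
                continue  # flat-flat segment: no defined elbow here
            ratio = np.inf
        else:
            ratio = num / den
        key = labels[b].item() if hasattr(labels[b], "item") else labels[b]
        ratios[key] = ratio
    report.ratios = ratios
    if not ratios:
        report.no_solution = True
        return report
    report.infinite_ratio = any(np.isinf(r) for r in ratios.values())

    ordered = sorted(ratios.items(), key=lambda kv: (-kv[1], kv[0]))
    report.selected, report.best_ratio = ordered[0]
    if len(ordered) > 1:
        report.second, report.second_ratio = ordered[1]
        if report.best_ratio == ordered[1][1]:
            report.tie = True
    return report


def selection_table(logliks: dict, n_groups: int, n_obs: int,
                    spec: StructuralSpec) -> pd.DataFrame:
    """Assemble the per-K selection table.

    ``logliks`` maps the number of clusters K to the observed (single-
    indicator) log-likelihood of the best fit with that K.
    """
    ks = sorted(logliks)
    rows = []
    for k in ks:
        P = count_free_params(k, n_groups, spec)
        ll = logliks[k]
        rows.append({"K": k, "loglik": ll, "P": P,
                     "BIC_G": bic_g(ll, P, n_groups),
                     "BIC_N": bic(ll, P, n_obs),
                     "AIC": aic(ll, P)})
    table = pd.DataFrame(rows)
    report = chull_select(table["P"].to_numpy(), table["loglik"].to_numpy(),
                          table["K"].to_numpy())
    table["on_hull"] = table["K"].isin(report.hull)
    table["scree_ratio"] = table["K"].map(report.ratios)
    return table


def select_n_clusters(table: pd.DataFrame) -> dict:
    """Selected K per criterion; information-criterion ties break toward
    smaller K.  The CHull entry is None when the scree test has no solution."""
    out = {}
    for crit in ("BIC_G", "AIC"):
        best = table[crit].min()
        out[crit] = int(table.loc[table[crit] == best, "K"].min())
    report = chull_select(table["P"].to_numpy(), table["loglik"].to_numpy(),
                          table["K"].to_numpy())
    selected = report.selected
    # infinite-ratio remedy: an infinite maximal ratio flags a model whose
    # successor adds no fit; fall back to the second-largest ratio when one
    # exists (the scree-plot elbow it points to)
    if (selected is not None and np.isinf(report.best_ratio)
            and report.second is not None and np.isfinite(report.second_ratio)):
        selected = report.second
    out["CHull"] = None if selected is None else int(selected)
    out["CHull_report"] = report
    return out


def plot_chull(table: pd.DataFrame, path=None):
    """Scree-style plot of logL against P with the hull marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["P"], table["loglik"], "o", color="grey", label="models")
    hull = table[table["on_hull"]]
    ax.plot(hull["P"], hull["loglik"], "-o", color="C0", label="upper convex hull")
    for _, row in table.iterrows():
        ax.annotate(f"K={int(row['K'])}", (row["P"], row["loglik"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("number of free parameters")
    ax.set_ylabel("observed log-likelihood")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
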