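"""End-to-end estimator and simulation-study runner.

:class:`MixMLSEM` ties the three estimation steps together in the
statsmodels idiom: construct the model from a data frame plus measurement
and structural specifications, call :meth:`MixMLSEM.fit`, and receive a
:class:`MixMLSEMResults` carrying the per-factor measurement posteriors,
the Croon-corrected covariances, the mixture fits over a range of cluster
numbers and the model-selection table.

:func:`run_simulation_study` replays the factorial simulation design at a
chosen (typically reduced) scale: per cell and replicate it generates data,
runs the pipeline with the true number of clusters (study-1 mode) or a
range of cluster numbers (study-2 mode), and appends recovery/selection
outcomes to a tidy results table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import croon as croon_mod
from . import evaluate as eval_mod
from .mlcfa import center_within_group, extract_factor_scores, fit_all_blocks
from .mixture import GroupMixtureSEM
from .select import select_n_clusters, selection_table
from .simulate import SimulationDesign, generate_dataset
from .specs import MCMCSettings, MeasurementSpec, StructuralSpec

logger = logging.getLogger(__name__)

__all__ = [
    "MixMLSEM",
    "MixMLSEMResults",
    "PipelineConfig",
    "run_pipeline",
    "run_simulation_study",
    "aggregate_margins",
    "REPLICATION_MCMC",
]

# scaled-down sampler settings used by the replication runner
REPLICATION_MCMC = MCMCSettings(chains=2, iterations=1000, burn_in=500)


@dataclass
class MixMLSEMResults:
    """Everything produced by one pipeline run."""

    model: "MixMLSEM"
    blocks: list                       # per-factor MLCFAResults
    scores: pd.DataFrame
    si_params: croon_mod.SingleIndicatorParams
    covs: croon_mod.GroupFactorCov
    fits: dict                         # K -> GroupMixtureResults
    selection: pd.DataFrame | None
    selected: dict | None
    manifest: dict = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        """Number of clusters preferred by BIC with group-level sample size."""
        if self.selected is None:
            return next(iter(self.fits))
        return self.selected["BIC_G"]

    @property
    def best_fit(self):
        return self.fits[self.best_k]

    def summary(self) -> str:
        lines = ["Mixture multilevel SEM", "=" * 46]
        lines.append(f"groups: {self.covs.n_groups}   factors: {self.covs.n_factors}   "
                     f"individuals: {len(self.scores)}")
        conv = all(b.converged for b in self.blocks)
        lines.append(f"measurement step converged: {conv}")
        if self.selection is not None:
            lines += ["", "model selection:",
                      self.selection.round(2).to_string(index=False)]
            lines.append(f"selected K — BIC_G: {self.selected['BIC_G']}, "
                         f"AIC: {self.selected['AIC']}, "
                         f"CHull: {self.selected['CHull']}")
        lines += ["", self.best_fit.summary()]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Serialize all artifacts (CSV/JSON) plus a run manifest."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for block in self.blocks:
            block.to_json(out / f"mlcfa_{block.factor}.json")
        self.scores.to_csv(out / "factor_scores.csv", index=False)
        self.si_params.to_frame().to_csv(out / "single_indicator_params.csv", index=False)
        self.covs.to_json(out / "group_factor_covs.json")
        for k, fit in self.fits.items():
            with open(out / f"mixture_k{k}.json", "w") as fh:
                json.dump(fit.to_dict(), fh)
        if self.selection is not None:
            self.selection.to_csv(out / "selection_table.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


class MixMLSEM:
    """Three-step mixture multilevel SEM estimator.

    Parameters
    ----------
    data : DataFrame
        One row per individual: a ``group`` column, optional ``id`` and the
        item columns named in ``measurement_spec``.  Centering within groups
        is applied internally.
    measurement_spec : MeasurementSpec
    structural_spec : StructuralSpec
        Factor order must match the measurement spec's factors.
    """

    def __init__(self, data: pd.DataFrame, measurement_spec: MeasurementSpec,
                 structural_spec: StructuralSpec):
        if list(measurement_spec.factors) != list(structural_spec.factor_order):
            raise ValueError("measurement and structural specs disagree on factors")
        self.measurement_spec = measurement_spec
        self.structural_spec = structural_spec
        items = [i for f in measurement_spec.factors
                 for i in measurement_spec.items_of(f)]
        self.data = center_within_group(data, items)

    @classmethod
    def from_csv(cls, path, measurement_spec, structural_spec) -> "MixMLSEM":
        return cls(pd.read_csv(path), measurement_spec, structural_spec)

    def fit(self, k_range=(1, 2, 3, 4), settings: MCMCSettings | None = None,
            n_starts: int = 50, tol: float = 1e-6, max_iter: int = 500,
            seed: int = 0, select: bool = True) -> MixMLSEMResults:
        """Run measurement step, Croon correction and mixture fits.

        ``k_range`` is an iterable of cluster numbers; with a single value no
        selection table is built unless ``select`` is forced and at least
        three models are available.
        """
        t0 = time.time()
        settings = settings if settings is not None else MCMCSettings(seed=seed)
        blocks = fit_all_blocks(self.data, self.measurement_spec, settings)
        scores = extract_factor_scores(blocks)
        si = croon_mod.single_indicator_params(scores, self.measurement_spec.factors)
        covs = croon_mod.croon_corrected_cov(scores, si)
        model = GroupMixtureSEM(covs, self.structural_spec)
        fits, logliks = {}, {}
        for k in sorted(set(int(k) for k in k_range)):
            fit = model.fit(k, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed)
            fit.observed_loglik(scores, si)
            fits[k] = fit
            logliks[k] = fit.loglik_obs
        table = selected = None
        if select and len(fits) >= 3:
            table = selection_table(logliks, covs.n_groups, int(np.sum(covs.n_g)),
                                    self.structural_spec)
            selected = select_n_clusters(table)
        manifest = {
            "seed": seed, "k_range": sorted(fits), "n_starts": n_starts,
            "tol": tol, "max_iter": max_iter, "mcmc": settings.to_dict(),
            "n_groups": int(covs.n_groups), "n_rows": int(len(self.data)),
            "elapsed_s": round(time.time() - t0, 2),
        }
        return MixMLSEMResults(model=self, blocks=blocks, scores=scores,
                               si_params=si, covs=covs, fits=fits,
                               selection=table, selected=selected,
                               manifest=manifest)


# ---------------------------------------------------------------------------
# configuration-file driven runs

@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see the YAML schema in the docs)."""

    data_path: str
    measurement: dict
    structural: dict
    k_min: int = 1
    k_max: int = 4
    n_starts: int = 50
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    mcmc: dict = field(default_factory=dict)
    output_dir: str = "mixmlsem_out"

    def __post_init__(self):
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need k_max >= k_min >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def measurement_spec(self) -> MeasurementSpec:
        m = self.measurement
        return MeasurementSpec(
            factor_blocks={f: list(v["items"]) for f, v in m["factors"].items()},
            marker_items={f: v.get("marker", v["items"][0])
                          for f, v in m["factors"].items()},
            random_loading_items={f: list(v.get("random_loadings", []))
                                  for f, v in m["factors"].items()},
            random_uniqueness_items={f: list(v.get("random_uniquenesses", []))
                                     for f, v in m["factors"].items()},
            residual_cov_pairs=[tuple(p) for p in m.get("residual_cov_pairs", [])],
            random_factor_variance={f: bool(v.get("random_factor_variance", True))
                                    for f, v in m["factors"].items()},
        )

    def structural_spec(self) -> StructuralSpec:
        s = self.structural
        return StructuralSpec(
            factor_order=list(s["factor_order"]),
            free_paths=[tuple(p) for p in s["paths"]],
            exogenous=list(s["exogenous"]),
        )


def run_pipeline(config: PipelineConfig) -> MixMLSEMResults:
    """Execute a configured run and serialize every artifact."""
    model = MixMLSEM.from_csv(config.data_path, config.measurement_spec(),
                              config.structural_spec())
    settings = MCMCSettings(seed=config.seed, **config.mcmc)
    res = model.fit(k_range=range(config.k_min, config.k_max + 1),
                    settings=settings, n_starts=config.n_starts,
                    tol=config.tol, max_iter=config.max_iter, seed=config.seed)
    res.manifest["config"] = asdict(config)
    res.save(config.output_dir)
    return res


# ---------------------------------------------------------------------------
# simulation-study replication

def _derive_seed(master: int, *key) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _rmse_from_blocks(blocks, truth) -> tuple:
    """RMSE of group-specific non-invariant loading/uniqueness estimates."""
    lam_est = np.stack([b.group_loadings[:, 1:3] for b in blocks], axis=1)
    th_est = np.stack([b.group_uniquenesses[:, 1:3] for b in blocks], axis=1)
    rmse_l = eval_mod.rmse_measurement(lam_est, truth.noninvariant_loadings())
    rmse_t = eval_mod.rmse_measurement(th_est, truth.noninvariant_uniquenesses())
    return rmse_l, rmse_t


def _run_replicate(cell: dict, ci: int, rep: int, rep_seed: int, mode: str,
                   k_range, settings: MCMCSettings, n_starts: int,
                   check_local_maximum: bool) -> dict:
    """One generate-fit-evaluate replicate (isolated so failures stay local)."""
    mspec = MeasurementSpec.simulation_default()
    sspec = StructuralSpec.four_factor_default()
    design = SimulationDesign(**{**cell, "seed": rep_seed})
    row = {**cell, "cell": ci, "replicate": rep, "seed": rep_seed}
    t0 = time.time()
    try:
        data, truth = generate_dataset(design)
        model = MixMLSEM(data, mspec, sspec)
        ks = [design.n_clusters] if mode == "study1" else list(k_range)
        res = model.fit(k_range=ks, settings=settings, n_starts=n_starts,
                        seed=rep_seed, select=(mode == "study2"))
        fit = res.fits[design.n_clusters]
        rmse_l, rmse_t = _rmse_from_blocks(res.blocks, truth)
        report = eval_mod.evaluate_fit(
            fit, truth, covs=res.covs, rmse_lambda=rmse_l,
            rmse_theta=rmse_t, check_local_maximum=check_local_maximum)
        row.update(report.to_row())
        row["step1_converged"] = all(b.converged for b in res.blocks)
        if mode == "study2":
            row["selected_BIC_G"] = res.selected["BIC_G"]
            row["selected_AIC"] = res.selected["AIC"]
            row["selected_CHull"] = res.selected["CHull"]
            for crit in ("BIC_G", "AIC", "CHull"):
                row[f"correct_{crit}"] = bool(row[f"selected_{crit}"]
                                              == design.n_clusters)
        row["failed"] = False
    except Exception as err:  # noqa: BLE001 - per-replicate isolation
        logger.exception("cell %d replicate %d failed", ci, rep)
        row["failed"] = True
        row["error"] = f"{type(err).__name__}: {err}"
    row["elapsed_s"] = round(time.time() - t0, 2)
    return row


def run_simulation_study(designs, replicates: int = 1, mode: str = "study1",
                         k_range=range(1, 7), settings: MCMCSettings | None = None,
                         n_starts: int = 50, seed: int = 0,
                         check_local_maximum: bool = False,
                         n_jobs: int = 1) -> pd.DataFrame:
    """Generate-fit-evaluate loop over design cells.

    ``designs`` is an iterable of :class:`SimulationDesign` (their ``seed``
    fields are overwritten from the master ``seed``).  In study-1 mode the
    mixture is fitted with the true number of clusters and recovery metrics
    are recorded; in study-2 mode cluster numbers in ``k_range`` are fitted
    and the selected K per criterion is recorded as well.  Per-replicate
    failures are logged and recorded, not fatal.

    Parallelism (``n_jobs``) is across replicates only; each replicate is
    single-threaded and derives its own seed stream from the master seed,
    so results are identical for any ``n_jobs``.
    """
    if mode not in ("study1", "study2"):
        raise ValueError("mode must be 'study1' or 'study2'")
    settings = settings if settings is not None else REPLICATION_MCMC
    jobs = []
    for ci, base in enumerate(designs):
        cell = {k: v for k, v in base.to_dict().items() if k != "seed"}
        for rep in range(replicates):
            jobs.append((cell, ci, rep, _derive_seed(seed, ci, rep)))
    args = dict(mode=mode, k_range=list(k_range), settings=settings,
                n_starts=n_starts, check_local_maximum=check_local_maximum)
    if n_jobs == 1:
        rows = [_run_replicate(*job, **args) for job in jobs]
    else:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_replicate)(*job, **args) for job in jobs)
    return pd.DataFrame(rows)


def aggregate_margins(results: pd.DataFrame, factors, values) -> pd.DataFrame:
    """Factor-level margins (mean per level), mirroring the study's summary
    tables: one row per (factor, level) with the mean of each value column."""
    ok = results[~results.get("failed", False).astype(bool)] \
        if "failed" in results.columns else results
    out = []
    for fac in factors:
        grp = ok.groupby(fac)[list(values)].mean().reset_index()
        grp.insert(0, "factor", fac)
        grp = grp.rename(columns={fac: "level"})
        out.append(grp)
    return pd.concat(out, ignore_index=True)
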