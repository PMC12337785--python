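import numpy as np
import pandas as pd
import pytest

from mixmlsem.simulate import SimulationDesign, generate_dataset
from mixmlsem.specs import MCMCSettings, MeasurementSpec, StructuralSpec


@pytest.fixture(scope="session")
def four_factor_spec():
    return StructuralSpec.four_factor_default()


@pytest.fixture(scope="session")
def measurement_spec():
    return MeasurementSpec.simulation_default()


@pytest.fixture(scope="session")
def short_mcmc():
    """Sampler settings small enough for unit tests."""
    return MCMCSettings(chains=2, iterations=600, burn_in=300, seed=7)


@pytest.fixture(scope="session")
def small_fixed_dataset():
    """One fixed-sampling dataset from the study design (small but realistic)."""
    design = SimulationDesign(n_groups=48, n_clusters=2, small_n=25, large_n=100,
                              small_prop=0.5, beta=0.3, reliability="high",
                              sampling="fixed", seed=1234)
    data, truth = generate_dataset(design)
    return design, data, truth


@pytest.fixture(scope="session")
def easy_regime_study():
    """Ten replicates of the easiest study cell, fitted end to end.

    beta = 0.4, K = 2, all groups of 200 rows, fixed sampling, high
    reliability — shared by the selection, recovery and local-maximum
    checks.
    """
    from mixmlsem.pipeline import run_simulation_study

    cells = [SimulationDesign(n_groups=48, n_clusters=2, small_prop=0.0,
                              large_n=200, beta=0.4, reliability="high",
                              sampling="fixed")]
    return run_simulation_study(cells, replicates=10, mode="study2",
                                k_range=range(1, 5), seed=20250728,
                                check_local_maximum=True)


@pytest.fixture()
def single_factor_data():
    """Hand-built single-factor data with known latent scores.

    High-information regime: 5 items, known loadings, small unique variances,
    60 groups of 40 — used as the oracle check that posterior factor scores
    track the generating latent variable.
    """
    rng = np.random.default_rng(99)
    G, n, lam = 60, 40, np.array([1.0, 0.8, 0.7, 0.6, 0.9])
    theta = np.full(5, 0.05)
    rows = []
    eta_all = []
    for g in range(1, G + 1):
        eta = rng.standard_normal(n)
        eta -= eta.mean()
        X = eta[:, None] * lam[None, :] + rng.standard_normal((n, 5)) * np.sqrt(theta)
        X -= X.mean(axis=0)
        df = pd.DataFrame(X, columns=[f"y{j}" for j in range(1, 6)])
        df.insert(0, "id", np.arange(1, n + 1))
        df.insert(0, "group", g)
        rows.append(df)
        eta_all.append(eta)
    return pd.concat(rows, ignore_index=True), np.concatenate(eta_all)
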