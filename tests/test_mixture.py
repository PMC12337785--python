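import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from mixmlsem.croon import GroupFactorCov, SingleIndicatorParams
from mixmlsem.mixture import (
    EmptyClusterError,
    GroupMixtureSEM,
    MixtureParams,
    e_step,
    fit_mixture,
    hard_partition,
    loglik_eta,
    m_step,
    observed_loglik,
)
from mixmlsem.simulate import SimulationDesign, generate_dataset, sample_group_structure, generate_group_parameters
from mixmlsem.specs import StructuralSpec


def covs_from_truth(truth):
    """Use the generating factor covariances as if they were Step-2 output."""
    return GroupFactorCov(
        groups=np.arange(1, truth.n_groups + 1),
        factors=["F1", "F2", "F3", "F4"],
        phi_s2=truth.Phi_true.copy(),
        cov_F=truth.Phi_true.copy(),
        n_g=truth.group_sizes.copy(),
    )


@pytest.fixture(scope="module")
def truth_covs(four_factor_spec=None):
    d = SimulationDesign(n_groups=48, n_clusters=2, small_prop=0.0, large_n=200,
                         beta=0.4, reliability="high", seed=42)
    sizes, clusters = sample_group_structure(d)
    truth = generate_group_parameters(d, clusters, sizes)
    return truth, covs_from_truth(truth)


def two_group_toy():
    """Hand-sized instance: 2 groups, Q = 2, one path F1 -> F2."""
    spec = StructuralSpec(factor_order=["F1", "F2"], free_paths=[("F1", "F2")],
                          exogenous=["F1"])
    phi = np.array([
        [[1.0, 0.5], [0.5, 1.2]],
        [[0.9, -0.2], [-0.2, 1.1]],
    ])
    covs = GroupFactorCov(groups=np.array([1, 2]), factors=["F1", "F2"],
                          phi_s2=phi, cov_F=phi.copy(), n_g=np.array([30, 50]))
    return spec, covs


class TestESTep:
    def test_single_cluster_gives_unit_memberships(self):
        spec, covs = two_group_toy()
        params, _ = m_step(np.ones((2, 1)), covs, spec)
        z = e_step(params, covs)
        assert np.allclose(z, 1.0)

    def test_identical_components_give_uniform_memberships(self):
        spec, covs = two_group_toy()
        params, _ = m_step(np.ones((2, 1)), covs, spec)
        dup = MixtureParams(pi=np.array([0.5, 0.5]),
                            B=np.repeat(params.B, 2, axis=0),
                            Psi=np.repeat(params.Psi, 2, axis=1))
        z = e_step(dup, covs)
        assert np.allclose(z, 0.5)

    def test_matches_bruteforce_density_oracle(self):
        # posteriors must equal direct evaluation of the component densities,
        # each raised to the group size
        spec, covs = two_group_toy()
        rng = np.random.default_rng(0)
        B = np.zeros((2, 2, 2))
        B[0, 1, 0], B[1, 1, 0] = 0.4, -0.1
        Psi = np.zeros((2, 2, 2, 2))
        for g in range(2):
            for k in range(2):
                M = np.eye(2) - B[k]
                A = M @ covs.phi_s2[g] @ M.T
                Psi[g, k] = np.array([[A[0, 0], 0.0], [0.0, A[1, 1]]])
        params = MixtureParams(pi=np.array([0.3, 0.7]), B=B, Psi=Psi)
        z = e_step(params, covs)
        # brute force in plain numpy
        expected = np.empty((2, 2))
        for g in range(2):
            logw = []
            for k in range(2):
                M = np.eye(2) - B[k]
                phi_gk = np.linalg.inv(M) @ Psi[g, k] @ np.linalg.inv(M).T
                dens = (
                    -np.log(2 * np.pi)
                    - 0.5 * np.log(np.linalg.det(phi_gk))
                    - 0.5 * np.trace(covs.phi_s2[g] @ np.linalg.inv(phi_gk))
                )
                logw.append(np.log(params.pi[k]) + covs.n_g[g] * dens)
            expected[g] = np.exp(logw - logsumexp(logw))
        assert np.allclose(z, expected, atol=1e-12)


class TestMStep:
    def test_single_group_saturated_fit_is_exact(self):
        spec, covs = two_group_toy()
        one = GroupFactorCov(groups=covs.groups[:1], factors=covs.factors,
                             phi_s2=covs.phi_s2[:1], cov_F=covs.cov_F[:1],
                             n_g=covs.n_g[:1])
        params, _ = m_step(np.ones((1, 1)), one, spec)
        assert np.allclose(params.implied_cov()[0, 0], one.phi_s2[0], atol=1e-12)

    def test_hard_partition_recovers_generating_regressions(self, truth_covs):
        truth, covs = truth_covs
        spec = StructuralSpec.four_factor_default()
        z = np.zeros((truth.n_groups, 2))
        z[np.arange(truth.n_groups), truth.cluster_of_group] = 1.0
        params, _ = m_step(z, covs, spec)
        assert np.abs(params.B - truth.B_true).max() < 0.05

    def test_equal_soft_weights_give_identical_clusters(self, truth_covs):
        _, covs = truth_covs
        spec = StructuralSpec.four_factor_default()
        z = np.full((covs.n_groups, 3), 1.0 / 3.0)
        params, _ = m_step(z, covs, spec)
        assert np.allclose(params.B[0], params.B[1])
        assert np.allclose(params.B[1], params.B[2])

    def test_empty_cluster_raises_restart_signal(self):
        spec, covs = two_group_toy()
        z = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(EmptyClusterError):
            m_step(z, covs, spec)


class TestFitMixture:
    def test_easy_regime_recovers_partition_exactly(self, truth_covs):
        truth, covs = truth_covs
        fit = fit_mixture(covs, StructuralSpec.four_factor_default(), 2,
                          n_starts=20, seed=0)
        part = fit.hard_partition()
        from mixmlsem.evaluate import adjusted_rand_index
        assert adjusted_rand_index(part, truth.cluster_of_group) == 1.0
        assert fit.converged

    def test_k1_equals_pooled_path_model_oracle(self, truth_covs):
        # independent oracle: per-equation regressions on the size-weighted
        # pooled covariance matrix
        truth, covs = truth_covs
        fit = fit_mixture(covs, StructuralSpec.four_factor_default(), 1, seed=0)
        w = covs.n_g / covs.n_g.sum()
        S_bar = np.einsum("g,gab->ab", w, covs.phi_s2)
        # F3 ~ F1 + F2 ; F4 ~ F1 + F3  (orders: F1, F2, F3, F4)
        b3 = np.linalg.solve(S_bar[np.ix_([0, 1], [0, 1])], S_bar[[0, 1], 2])
        b4 = np.linalg.solve(S_bar[np.ix_([0, 2], [0, 2])], S_bar[[0, 2], 3])
        assert fit.params.B[0, 2, [0, 1]] == pytest.approx(b3, abs=1e-10)
        assert fit.params.B[0, 3, [0, 2]] == pytest.approx(b4, abs=1e-10)

    def test_label_permutation_leaves_loglik_unchanged(self, truth_covs):
        _, covs = truth_covs
        fit = fit_mixture(covs, StructuralSpec.four_factor_default(), 2,
                          n_starts=5, seed=1)
        p = fit.params
        swapped = MixtureParams(pi=p.pi[::-1].copy(), B=p.B[::-1].copy(),
                                Psi=p.Psi[:, ::-1].copy())
        assert loglik_eta(swapped, covs) == pytest.approx(fit.loglik, abs=1e-8)

    def test_loglik_eta_is_monotone_over_em(self, truth_covs):
        # re-run EM manually from a poor start and track the trajectory
        _, covs = truth_covs
        spec = StructuralSpec.four_factor_default()
        model = GroupMixtureSEM(covs, spec)
        rng = np.random.default_rng(3)
        z = np.zeros((covs.n_groups, 2))
        z[np.arange(covs.n_groups), rng.integers(0, 2, covs.n_groups)] = 1.0
        params, _ = m_step(z, covs, spec)
        lls = [loglik_eta(params, covs)]
        for _ in range(40):
            z = e_step(params, covs)
            params, _ = m_step(z, covs, spec)
            lls.append(loglik_eta(params, covs))
        assert np.all(np.diff(lls) > -1e-7)

    def test_more_groups_than_clusters_required(self):
        spec, covs = two_group_toy()
        with pytest.raises(ValueError):
            GroupMixtureSEM(covs, spec).fit(3)


class TestHardPartition:
    def test_modal_assignment_and_tie_break(self):
        z = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        assert hard_partition(z).tolist() == [0, 0, 1]

    def test_single_occupied_cluster_is_representable(self):
        z = np.array([[0.6, 0.4], [0.7, 0.3], [0.55, 0.45]])
        part = hard_partition(z)
        assert len(np.unique(part)) == 1


class TestObservedLoglik:
    @staticmethod
    def scores_and_params(phi, n_rows, seed=0, lam=1.0, theta=0.0):
        rng = np.random.default_rng(seed)
        frames, means = [], []
        for g, n in enumerate(n_rows, start=1):
            m = rng.multivariate_normal(np.zeros(2), phi[g - 1], size=n)
            m -= m.mean(axis=0)
            df = pd.DataFrame({"group": g, "F1_mean": m[:, 0], "F1_sd": 0.0,
                               "F2_mean": m[:, 1], "F2_sd": 0.0})
            frames.append(df)
            means.append(m)
        scores = pd.concat(frames, ignore_index=True)
        G = len(n_rows)
        si = SingleIndicatorParams(
            groups=np.arange(1, G + 1), factors=["F1", "F2"],
            lambda_hat=np.full((G, 2), lam),
            theta_hat=np.full((G, 2), theta),
            phi_hat=np.ones((G, 2)))
        return scores, si, means

    def test_identity_measurement_reduces_to_score_density(self):
        spec, covs = two_group_toy()
        params, _ = m_step(np.ones((2, 1)), covs, spec)
        scores, si, means = self.scores_and_params(covs.phi_s2, [30, 50], seed=5)
        ll = observed_loglik(params, scores, si)
        # direct per-row MVN log-density under the implied Phi_g1
        phi = params.implied_cov()[:, 0]
        expected = 0.0
        for g, m in enumerate(means):
            inv = np.linalg.inv(phi[g])
            _, logdet = np.linalg.slogdet(phi[g])
            quad = np.einsum("ni,ij,nj->n", m, inv, m)
            expected += np.sum(-np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_matches_bruteforce_mixture_of_rows(self):
        # 2 groups x 3 rows, Q = 2, K = 2, nontrivial measurement parameters
        spec, covs = two_group_toy()
        rng = np.random.default_rng(9)
        B = np.zeros((2, 2, 2))
        B[0, 1, 0], B[1, 1, 0] = 0.3, -0.2
        Psi = np.stack([np.stack([np.diag([1.0, 0.8]), np.diag([0.9, 1.1])])] * 2)
        params = MixtureParams(pi=np.array([0.4, 0.6]), B=B, Psi=Psi)
        frames = []
        for g in (1, 2):
            m = rng.standard_normal((3, 2))
            m -= m.mean(axis=0)
            frames.append(pd.DataFrame({
                "group": g, "F1_mean": m[:, 0], "F1_sd": 0.2,
                "F2_mean": m[:, 1], "F2_sd": 0.3}))
        scores = pd.concat(frames, ignore_index=True)
        si = SingleIndicatorParams(
            groups=np.array([1, 2]), factors=["F1", "F2"],
            lambda_hat=np.array([[0.8, 0.9], [0.7, 0.95]]),
            theta_hat=np.array([[0.2, 0.1], [0.25, 0.05]]),
            phi_hat=np.ones((2, 2)))
        ll = observed_loglik(params, scores, si)

        expected = 0.0
        phi = params.implied_cov()
        for gi, g in enumerate((1, 2)):
            m = scores.loc[scores.group == g, ["F1_mean", "F2_mean"]].to_numpy()
            m = m - m.mean(axis=0)
            logw = []
            for k in range(2):
                lam = np.diag(si.lambda_hat[gi])
                sig = lam @ phi[gi, k] @ lam + np.diag(si.theta_hat[gi])
                inv, (_, logdet) = np.linalg.inv(sig), np.linalg.slogdet(sig)
                row_ll = sum(-np.log(2 * np.pi) - 0.5 * logdet
                             - 0.5 * r @ inv @ r for r in m)
                logw.append(np.log(params.pi[k]) + row_ll)
            expected += logsumexp(logw)
        assert ll == pytest.approx(expected, rel=1e-10)
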