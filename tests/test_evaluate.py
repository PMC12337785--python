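import numpy as np
import pytest
from itertools import combinations

from mixmlsem.evaluate import (
    adjusted_rand_index,
    correct_classification_rate,
    evaluate_fit,
    local_maximum_flag,
    rmse_beta,
    rmse_measurement,
)
from mixmlsem.mixture import GroupMixtureResults, MixtureParams, fit_mixture
from mixmlsem.simulate import (SimulationDesign, generate_group_parameters,
                               sample_group_structure)
from mixmlsem.specs import StructuralSpec
from test_mixture import covs_from_truth


def ari_bruteforce(a, b):
    """Pair-counting definition of the adjusted Rand index."""
    n = len(a)
    same_a = {(i, j): a[i] == a[j] for i, j in combinations(range(n), 2)}
    same_b = {(i, j): b[i] == b[j] for i, j in combinations(range(n), 2)}
    n11 = sum(same_a[p] and same_b[p] for p in same_a)
    n00 = sum((not same_a[p]) and (not same_b[p]) for p in same_a)
    npairs = n * (n - 1) // 2
    sum_a = sum(same_a.values())
    sum_b = sum(same_b.values())
    expected = sum_a * sum_b / npairs + (npairs - sum_a) * (npairs - sum_b) / npairs
    return (n11 + n00 - expected) / (npairs - expected)


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_degenerate_single_cluster_estimate(self):
        assert adjusted_rand_index([0, 0, 0, 0], [0, 0, 1, 1]) == 0.0

    @pytest.mark.parametrize("a, b", [
        ([1, 1, 2, 2], [1, 2, 1, 2]),
        ([0, 0, 1, 1, 2, 2], [0, 1, 1, 2, 2, 0]),
        ([0, 1, 0, 1, 0, 1, 2], [2, 2, 1, 1, 0, 0, 0]),
    ])
    def test_matches_pair_counting_oracle(self, a, b):
        assert adjusted_rand_index(a, b) == pytest.approx(ari_bruteforce(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 1])


class TestCorrectClassification:
    def test_perfect_recovery(self):
        assert correct_classification_rate([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_label_swap_is_free(self):
        assert correct_classification_rate([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_one_of_48_misplaced(self):
        truth = np.repeat([0, 1], 24)
        est = truth.copy()
        est[7] = 1 - est[7]
        assert correct_classification_rate(est, truth) == pytest.approx(47 / 48)


class TestRMSE:
    def test_exact_estimates(self):
        x = np.random.default_rng(0).standard_normal((48, 2))
        assert rmse_measurement(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((48, 2))
        assert rmse_measurement(x + 0.05, x) == pytest.approx(0.05)

    def test_gaussian_perturbation_expectation(self):
        # N(0, 0.01) perturbations -> RMSE ~ 0.1 in expectation
        rng = np.random.default_rng(1)
        x = rng.standard_normal((48, 2))
        noisy = x + rng.normal(0, 0.1, size=x.shape)
        assert rmse_measurement(noisy, x) == pytest.approx(0.1, abs=0.02)


@pytest.fixture(scope="module")
def small_truth():
    d = SimulationDesign(n_groups=48, n_clusters=2, small_prop=0.0, large_n=200,
                         beta=0.3, reliability="high", seed=17)
    sizes, clusters = sample_group_structure(d)
    return generate_group_parameters(d, clusters, sizes)


def fake_fit(truth, B, z):
    params = MixtureParams(pi=z.mean(axis=0), B=B,
                           Psi=np.zeros((len(z), B.shape[0], 4, 4)))
    return GroupMixtureResults(model=type("M", (), {"spec": StructuralSpec.four_factor_default()})(),
                               params=params, z=z, loglik=0.0, n_iter=1,
                               converged=True, start_id=0,
                               start_logliks=np.zeros(1))


class TestRMSEBeta:
    def test_exact_estimates_and_label_swap(self, small_truth):
        truth = small_truth
        z = np.zeros((truth.n_groups, 2))
        z[np.arange(truth.n_groups), truth.cluster_of_group] = 1.0
        fit = fake_fit(truth, truth.B_true.copy(), z)
        assert all(v == 0.0 for k, v in rmse_beta(fit, truth).items()
                   if k.startswith("beta"))
        # swap both the memberships and the cluster parameters
        fit_sw = fake_fit(truth, truth.B_true[::-1].copy(), z[:, ::-1].copy())
        out = rmse_beta(fit_sw, truth)
        assert all(v == 0.0 for k, v in out.items() if k.startswith("beta"))
        assert not out["k_mismatch"]

    def test_worked_two_cluster_example(self, small_truth):
        # truth beta1 = (0, 0.3); estimates (0.1, 0.2) -> RMSE 0.1
        truth = small_truth
        z = np.zeros((truth.n_groups, 2))
        z[np.arange(truth.n_groups), truth.cluster_of_group] = 1.0
        B = truth.B_true.copy()
        B[0, 3, 0] = 0.1   # true 0.0
        B[1, 3, 0] = 0.2   # true 0.3
        out = rmse_beta(fake_fit(truth, B, z), truth)
        assert out["beta1"] == pytest.approx(0.1)
        assert out["beta2"] == 0.0


class TestLocalMaximumFlag:
    def test_threshold_rule(self, small_truth):
        truth = small_truth
        covs = covs_from_truth(truth)
        spec = StructuralSpec.four_factor_default()
        best = fit_mixture(covs, spec, 2, n_starts=10, seed=0)
        flag, proxy_ll = local_maximum_flag(best, covs, truth)
        assert flag is False
        assert proxy_ll <= best.loglik + 1e-6
        # artificially degrade the best fit beyond / within the tolerance
        import copy
        worse = copy.copy(best)
        worse.loglik = proxy_ll - 0.01
        assert local_maximum_flag(worse, covs, truth)[0] is True
        near = copy.copy(best)
        near.loglik = proxy_ll - 0.0005
        assert local_maximum_flag(near, covs, truth)[0] is False


class TestEvaluateFit:
    def test_report_fields_and_uncertainty(self, small_truth):
        truth = small_truth
        covs = covs_from_truth(truth)
        fit = fit_mixture(covs, StructuralSpec.four_factor_default(), 2,
                          n_starts=10, seed=0)
        rep = evaluate_fit(fit, truth, covs=covs, check_local_maximum=True)
        assert rep.ari == 1.0 and rep.pct_correct == 1.0
        assert not rep.one_cluster_collapse
        assert rep.local_maximum is False
        # degenerate memberships <=> zero classification uncertainty
        assert (rep.uncertainty == 0.0) == bool(
            np.all(np.isclose(fit.z.max(axis=1), 1.0)))

    def test_easy_regime_recovery_and_local_maxima(self, easy_regime_study):
        # mean ARI in the easiest cell approaches 1 and the multistart EM
        # essentially never lags the true-partition proxy
        ok = easy_regime_study[~easy_regime_study["failed"]]
        assert ok["ari"].mean() > 0.95
        assert ok["local_maximum"].mean() <= 0.1

    def test_metrics_invariant_to_group_reordering(self, small_truth):
        truth = small_truth
        perm = np.random.default_rng(2).permutation(truth.n_groups)
        est = truth.cluster_of_group.copy()
        assert adjusted_rand_index(est[perm], truth.cluster_of_group[perm]) == \
            adjusted_rand_index(est, truth.cluster_of_group)
        assert correct_classification_rate(est[perm], truth.cluster_of_group[perm]) \
            == correct_classification_rate(est, truth.cluster_of_group)
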