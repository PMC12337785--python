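import numpy as np
import pytest

from mixmlsem.simulate import (
    SimulationDesign,
    build_cluster_regressions,
    generate_dataset,
    generate_group_parameters,
    sample_group_structure,
)
from mixmlsem.specs import StructuralSpec

IDX = {f: i for i, f in enumerate(StructuralSpec.four_factor_default().factor_order)}


def beta_of(B, label):
    paths = {"beta1": ("F1", "F4"), "beta2": ("F1", "F3"),
             "beta3": ("F2", "F3"), "beta4": ("F3", "F4")}
    s, t = paths[label]
    return B[IDX[t], IDX[s]]


class TestClusterRegressions:
    def test_two_clusters_zero_pattern(self):
        B = build_cluster_regressions(2, 0.3)
        assert beta_of(B[0], "beta1") == 0.0
        assert all(beta_of(B[0], b) == 0.3 for b in ("beta2", "beta3", "beta4"))
        assert beta_of(B[1], "beta2") == 0.0
        assert all(beta_of(B[1], b) == 0.3 for b in ("beta1", "beta3", "beta4"))

    def test_four_clusters_one_zero_each(self):
        B = build_cluster_regressions(4, 0.4)
        beta2 = [beta_of(B[k], "beta2") for k in range(4)]
        assert sorted(beta2) == [0.0, 0.4, 0.4, 0.4]
        for k in range(4):
            vals = [beta_of(B[k], b) for b in ("beta1", "beta2", "beta3", "beta4")]
            assert vals.count(0.0) == 1 and vals.count(0.4) == 3

    def test_relaxed_single_cluster(self):
        B = build_cluster_regressions(1, 0.2, strict=False)
        assert beta_of(B[0], "beta1") == 0.0
        assert all(beta_of(B[0], b) == 0.2 for b in ("beta2", "beta3", "beta4"))

    def test_strict_rejects_odd_k(self):
        with pytest.raises(ValueError):
            build_cluster_regressions(3, 0.3)

    def test_pairwise_cluster_difference_is_two_coefficients(self):
        B = build_cluster_regressions(4, 0.3)
        for a in range(4):
            for b in range(a + 1, 4):
                assert np.sum(B[a] != B[b]) == 2
                assert np.abs(B[a] - B[b]).max() == pytest.approx(0.3)

    def test_strictly_lower_triangular(self):
        B = build_cluster_regressions(2, 0.3)
        for k in range(2):
            assert np.allclose(B[k], np.tril(B[k], k=-1))


class TestGroupStructure:
    def test_quarter_small(self):
        d = SimulationDesign(n_groups=48, n_clusters=2, small_n=25, large_n=100,
                             small_prop=0.25, seed=5)
        sizes, clusters = sample_group_structure(d)
        for k in range(2):
            in_k = sizes[clusters == k]
            assert len(in_k) == 24
            assert np.sum(in_k == 25) == 6 and np.sum(in_k == 100) == 18

    @pytest.mark.parametrize("prop, expected", [(0.0, 100), (1.0, 25)])
    def test_degenerate_proportions(self, prop, expected):
        d = SimulationDesign(n_groups=48, small_prop=prop, small_n=25, large_n=100)
        sizes, _ = sample_group_structure(d)
        assert np.all(sizes == expected)

    def test_unbalanced_group_count_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_groups=50, n_clusters=4)


class TestGroupParameters:
    def test_reliability_levels(self):
        for rel, lam, th in [("high", 0.6, 0.4), ("low", 0.4, 0.6)]:
            d = SimulationDesign(reliability=rel, seed=2)
            sizes, clusters = sample_group_structure(d)
            truth = generate_group_parameters(d, clusters, sizes)
            assert np.all(truth.Lambda_true[:, :, 0] == 1.0)      # marker
            assert np.all(truth.Lambda_true[:, :, 3:] == lam)     # invariant
            assert np.all(truth.Theta_true[:, :, 0] == th)
            assert np.all(truth.Theta_true[:, :, 3:] == th)
            # non-invariant loadings actually vary across groups
            assert truth.Lambda_true[:, :, 1].std() > 0.1

    def test_zero_beta_residual_equals_total(self):
        d = SimulationDesign(beta=0.0, strict=False, seed=3)
        sizes, clusters = sample_group_structure(d)
        truth = generate_group_parameters(d, clusters, sizes)
        # with all regressions zero the residual variance is the total variance
        i3, i4 = IDX["F3"], IDX["F4"]
        assert np.allclose(truth.Psi_true[:, i3, i3], truth.Phi_true[:, i3, i3])
        assert np.allclose(truth.Psi_true[:, i4, i4], truth.Phi_true[:, i4, i4])

    def test_sigma_positive_definite_and_groups_share_cluster_B(self):
        d = SimulationDesign(n_groups=48, n_clusters=4, beta=0.4, seed=4)
        _, truth = generate_dataset(d)
        eigmin = min(np.linalg.eigvalsh(s)[0] for s in truth.Sigma_true)
        assert eigmin > 0
        assert truth.B_true.shape == (4, 4, 4)

    def test_exogenous_moments_match_design(self):
        # across many groups the Wishart draws should reproduce the design's
        # realized moments: Var(F1/F2) mean ~0.952, SD ~0.166; Cov SD ~0.117
        d = SimulationDesign(n_groups=96, n_clusters=2, seed=11)
        v, c = [], []
        for seed in range(6):
            dd = SimulationDesign(n_groups=96, n_clusters=2, seed=seed)
            sizes, clusters = sample_group_structure(dd)
            truth = generate_group_parameters(dd, clusters, sizes)
            i1, i2 = IDX["F1"], IDX["F2"]
            v += truth.Psi_true[:, i1, i1].tolist() + truth.Psi_true[:, i2, i2].tolist()
            c += truth.Psi_true[:, i1, i2].tolist()
        v, c = np.asarray(v), np.asarray(c)
        assert len(v) >= 1000
        assert v.mean() == pytest.approx(0.952, abs=0.02)
        assert v.std() == pytest.approx(0.166, abs=0.02)
        assert c.mean() == pytest.approx(0.0, abs=0.02)
        assert c.std() == pytest.approx(0.117, abs=0.02)

    def test_impossible_residuals_error_out(self):
        d = SimulationDesign(beta=5.0, strict=False, seed=6)
        sizes, clusters = sample_group_structure(d)
        with pytest.raises(RuntimeError, match="residual"):
            generate_group_parameters(d, clusters, sizes, max_resample=10)


class TestGenerateDataset:
    def test_fixed_sampling_is_exact(self, small_fixed_dataset):
        design, data, truth = small_fixed_dataset
        items = [f"y{j}" for j in range(1, 21)]
        for g in (1, 17, 48):
            X = data.loc[data.group == g, items].to_numpy()
            assert np.abs(X.mean(axis=0)).max() < 1e-10
            S = X.T @ X / len(X)
            assert np.abs(S - truth.Sigma_true[g - 1]).max() < 1e-10

    def test_fixed_sampling_needs_enough_rows(self):
        d = SimulationDesign(small_n=10, small_prop=1.0, sampling="fixed", seed=7)
        with pytest.raises(ValueError, match="at least"):
            generate_dataset(d)

    def test_random_sampling_converges_to_sigma(self):
        # law of large numbers at a single very large group
        d = SimulationDesign(n_groups=2, n_clusters=2, strict=False,
                             large_n=100_000, small_prop=0.0,
                             sampling="random", seed=8)
        data, truth = generate_dataset(d)
        items = [f"y{j}" for j in range(1, 21)]
        X = data.loc[data.group == 1, items].to_numpy()
        S = np.cov(X, rowvar=False)
        assert np.abs(S - truth.Sigma_true[0]).max() < 0.05

    def test_same_seed_same_dataset(self):
        d = SimulationDesign(seed=9)
        a, ta = generate_dataset(d)
        b, tb = generate_dataset(d)
        assert a.equals(b)
        assert np.array_equal(ta.Sigma_true, tb.Sigma_true)

    def test_ground_truth_round_trip(self, tmp_path, small_fixed_dataset):
        _, _, truth = small_fixed_dataset
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = type(truth).from_json(p)
        assert np.allclose(back.Sigma_true, truth.Sigma_true)
        assert np.array_equal(back.cluster_of_group, truth.cluster_of_group)
        assert back.design.beta == truth.design.beta
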