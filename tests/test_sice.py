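import numpy as np
import pytest

import sicenet as sn
from sicenet.sice import count_arcs, default_lambda_bounds, penalized_objective


def grid_search_objective_max_2x2(S, lam, n=60):
    """Independent dense-grid maximisation of the penalised likelihood
    over 2x2 SPD matrices (parametrised by diagonal and off-diagonal)."""
    best = -np.inf
    for d1 in np.linspace(0.05, 3.0, n):
        for d2 in np.linspace(0.05, 3.0, n):
            m = np.sqrt(d1 * d2)
            for o in np.linspace(-0.99 * m, 0.99 * m, n):
                theta = np.array([[d1, o], [o, d2]])
                best = max(best, penalized_objective(theta, S, lam))
    return best


class TestEmpiricalCovariance:
    def test_two_point_hand_computation(self):
        cov = sn.empirical_covariance(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(cov.S, [[1.0, 1.0], [1.0, 1.0]])

    def test_identical_rows_zero_matrix(self):
        cov = sn.empirical_covariance(np.tile([1.0, 2.0, 3.0], (5, 1)))
        np.testing.assert_allclose(cov.S, 0.0)

    def test_brute_force_summation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 4))
        mu = x.mean(axis=0)
        S = np.zeros((4, 4))
        for row in x:
            d = row - mu
            S += np.outer(d, d)
        S /= 50
        np.testing.assert_allclose(sn.empirical_covariance(x).S, S, atol=1e-12)


class TestEstimateSparsePrecision:
    def test_unpenalized_mle_is_matrix_inverse(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 5))
        cov = sn.empirical_covariance(x)
        est = sn.estimate_sparse_precision(cov, lam=0.0)
        expected = np.linalg.inv(cov.S)
        assert np.abs(est.theta_hat - expected).max() / np.abs(expected).max() < 1e-6

    def test_singular_covariance_at_zero_lambda_rejected(self):
        cov = sn.empirical_covariance(np.array([[0.0, 0.0], [1.0, 1.0]]))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            sn.estimate_sparse_precision(cov, lam=0.0)

    def test_large_lambda_gives_diagonal_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 6))
        cov = sn.empirical_covariance(x)
        est = sn.estimate_sparse_precision(cov, lam=10.0)
        assert est.arc_count == 0

    def test_objective_attains_grid_search_maximum(self):
        S = np.array([[1.2, 0.5], [0.5, 0.9]])
        cov = sn.EmpiricalCovariance(S=S, mean=np.zeros(2), n=50)
        for lam in (0.05, 0.2):
            est = sn.estimate_sparse_precision(cov, lam=lam)
            grid_best = grid_search_objective_max_2x2(S, lam)
            assert est.objective_value >= grid_best - 1e-4

    def test_objective_beats_random_spd_perturbations(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((80, 4))
        cov = sn.empirical_covariance(x)
        est = sn.estimate_sparse_precision(cov, lam=0.1)
        for _ in range(1000):
            noise = rng.standard_normal((4, 4)) * 0.05
            cand = est.theta_hat + (noise + noise.T) / 2
            if np.linalg.eigvalsh(cand).min() <= 0:
                continue
            assert penalized_objective(cand, cov.S, 0.1) <= est.objective_value + 1e-9


class TestSweepLambdaToArcs:
    def test_target_zero_returns_diagonal(self, truth10):
        f = sn.sample_subjects(truth10, 200, seed=1)
        est = sn.sweep_lambda_to_arcs(sn.empirical_covariance(f.values), 0)
        assert est.arc_count == 0

    def test_full_graph_at_small_lambda(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((500, 5)) @ np.diag([1, 2, 1, 0.5, 1])
        x += 0.5 * rng.standard_normal((500, 1))  # shared factor: dense dependence
        est = sn.sweep_lambda_to_arcs(sn.empirical_covariance(x), 10)
        assert est.arc_count == 10

    def test_arc_counts_non_increasing_along_lambda_grid(self, truth10):
        f = sn.sample_subjects(truth10, 300, seed=2)
        cov = sn.empirical_covariance(f.values)
        lo, hi = default_lambda_bounds(cov)
        counts = [
            sn.estimate_sparse_precision(cov, lam).arc_count
            for lam in np.geomspace(lo, hi, 15)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBinarize:
    def test_identity_gives_empty_graph(self, partition10):
        est = sn.estimate_sparse_precision(
            sn.EmpiricalCovariance(S=np.eye(10), mean=np.zeros(10), n=50), lam=0.0
        )
        net = sn.binarize(est, partition10)
        assert net.arcs == 0

    def test_sign_blind_support(self, partition10):
        theta = np.eye(10)
        theta[0, 1] = theta[1, 0] = 0.3
        theta[0, 2] = theta[2, 0] = -0.2
        est = sn.PrecisionEstimate(theta_hat=theta, lam=0.1, arc_count=2, objective_value=0.0, converged=True)
        net = sn.binarize(est, partition10)
        assert net.arc_list() == [(1, 2), (1, 3)]

    def test_arc_count_matches_direct_nonzero_count(self, truth10):
        f = sn.sample_subjects(truth10, 100, seed=3)
        est = sn.sweep_lambda_to_arcs(sn.empirical_covariance(f.values), 12)
        net = sn.binarize(est, truth10.partition)
        off = est.theta_hat - np.diag(np.diag(est.theta_hat))
        assert net.arcs == np.count_nonzero(off) // 2


class TestCumulativePrecision:
    def test_weights_and_entries(self, truth10):
        f = sn.sample_subjects(truth10, 500, seed=4)
        cov = sn.empirical_covariance(f.values)
        levels = (5, 10, 20)
        cum = sn.cumulative_precision(cov, truth10.partition, arc_levels=levels)
        assert cum.weights == {5: 2.0, 10: 1.0, 20: 0.5}
        # cross-check: direct weighted sum of independently binarized estimates
        expected = np.zeros((10, 10))
        for n in levels:
            est = sn.sweep_lambda_to_arcs(cov, n)
            expected += (10.0 / n) * sn.binarize(est, truth10.partition).adjacency
        np.testing.assert_allclose(cum.theta_c, expected)

    def test_decided_weight_sum_for_standard_levels(self):
        # an edge surviving at every standard level accumulates
        # 10/10 + 10/25 + 10/50 + 10/75 + 10/100
        total = sum(sn.sice.inverse_arc_weight(n) for n in (10, 25, 50, 75, 100))
        np.testing.assert_allclose(total, 1.8333333333, atol=1e-9)

    def test_sparser_level_edges_dominate(self, truth10):
        f = sn.sample_subjects(truth10, 500, seed=4)
        cum = sn.cumulative_precision(
            sn.empirical_covariance(f.values), truth10.partition, arc_levels=(5, 20)
        )
        vals = cum.theta_c[np.triu_indices(10, k=1)]
        present = sorted(set(np.round(vals[vals > 0], 9)))
        # possible values: 0.5 (dense level only) and 2.5 (both); a sparse-
        # level survivor always exceeds a dense-only edge
        assert all(v in (0.5, 2.5) for v in present)


class TestTopArcs:
    def test_keeps_strongest(self, partition10):
        theta = np.eye(10)
        theta[0, 1] = theta[1, 0] = 0.9
        theta[2, 3] = theta[3, 2] = 0.3
        est = sn.PrecisionEstimate(theta_hat=theta, lam=0.0, arc_count=2, objective_value=0.0, converged=True)
        net = sn.top_arcs(est, partition10, 1)
        assert net.arc_list() == [(1, 2)]

    def test_k_equals_total_is_identity(self, truth10):
        f = sn.sample_subjects(truth10, 200, seed=6)
        est = sn.sweep_lambda_to_arcs(sn.empirical_covariance(f.values), 10)
        full = sn.binarize(est, truth10.partition)
        net = sn.top_arcs(est, truth10.partition, full.arcs)
        np.testing.assert_array_equal(net.adjacency, full.adjacency)

    def test_sort_and_slice_oracle(self, partition10):
        rng = np.random.default_rng(7)
        theta = np.eye(10)
        iu = np.triu_indices(10, k=1)
        w = rng.random(len(iu[0])) * (rng.random(len(iu[0])) < 0.4)
        theta[iu] = w
        theta += np.triu(theta, k=1).T
        est = sn.PrecisionEstimate(theta_hat=theta, lam=0.0, arc_count=int((w > 0).sum()), objective_value=0.0, converged=True)
        k = 5
        net = sn.top_arcs(est, partition10, k)
        pairs = [(i, j) for i, j in zip(*iu) if theta[i, j] > 0]
        pairs.sort(key=lambda ij: -theta[ij])
        expected = sorted((i + 1, j + 1) for i, j in pairs[:k])
        assert sorted(net.arc_list()) == expected

    def test_excessive_k_rejected(self, partition10):
        theta = np.eye(10)
        est = sn.PrecisionEstimate(theta_hat=theta, lam=0.0, arc_count=0, objective_value=0.0, converged=True)
        with pytest.raises(ValueError):
            sn.top_arcs(est, partition10, 1)
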