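"""Core model operations: energy, exact partition function oracle,
mean-field E-step, M-steps, MPM and the full EM fit."""

import itertools
import math

import numpy as np
import pytest

import hmrfclust as hc
from hmrfclust import hmrf
from hmrfclust.containers import (
    BinaryExpressionMatrix,
    HMRFParams,
    Partition,
    Posteriors,
)


def two_voxel_graph():
    return hc.build_graph(np.array([[0, 0, 0], [1, 0, 0]]))


class TestPottsEnergy:
    def test_zero_beta_gives_zero_energy(self, line_graph, rng):
        part = Partition(labels=rng.integers(1, 4, 3), n_clusters=3)
        assert hc.potts_energy(part, line_graph, np.zeros(3)) == 0.0

    def test_single_matching_edge_contributes_minus_beta(self):
        g = two_voxel_graph()
        part = Partition(labels=np.array([1, 1]), n_clusters=2)
        assert hc.potts_energy(part, g, np.array([2.0, 5.0])) == pytest.approx(-2.0)

    def test_mismatched_edge_contributes_nothing(self):
        g = two_voxel_graph()
        part = Partition(labels=np.array([1, 2]), n_clusters=2)
        assert hc.potts_energy(part, g, np.array([2.0, 5.0])) == 0.0

    def test_matches_brute_force_edge_sum(self, rng):
        g = hc.build_graph(hc.full_grid_coords((3, 2, 2)))
        beta = rng.random(3) * 2
        part = Partition(labels=rng.integers(1, 4, g.n_voxels), n_clusters=3)
        expected = -sum(
            beta[part.labels[i] - 1]
            for i, j in g.edges
            if part.labels[i] == part.labels[j]
        )
        assert hc.potts_energy(part, g, beta) == pytest.approx(expected)

    def test_beta_length_mismatch_raises(self):
        g = two_voxel_graph()
        part = Partition(labels=np.array([1, 1]), n_clusters=2)
        with pytest.raises(ValueError, match="beta"):
            hc.potts_energy(part, g, np.array([1.0]))


class TestExactLogPartition:
    def test_single_voxel_any_beta_gives_log_k(self):
        g = hc.build_graph(np.array([[0, 0, 0]]))
        for k in (1, 2, 5):
            z = hc.gibbs_log_partition_exact(g, np.full(k, 3.0), k)
            assert z == pytest.approx(math.log(k))

    def test_two_voxels_one_edge_closed_form(self):
        # 4 configurations: 2 matched (weight e^b each), 2 mismatched (weight 1)
        g = two_voxel_graph()
        b = 0.7
        z = hc.gibbs_log_partition_exact(g, np.array([b, b]), 2)
        assert z == pytest.approx(math.log(2 * math.exp(b) + 2))

    def test_zero_beta_gives_n_log_k(self):
        g = hc.build_graph(hc.full_grid_coords((2, 2, 1)))
        z = hc.gibbs_log_partition_exact(g, np.zeros(3), 3)
        assert z == pytest.approx(g.n_voxels * math.log(3))

    def test_refuses_large_state_space(self):
        g = hc.build_graph(hc.full_grid_coords((5, 5, 5)))
        with pytest.raises(ValueError, match="state space"):
            hc.gibbs_log_partition_exact(g, np.zeros(4), 4)


class TestEStep:
    def test_zero_beta_matches_mixture_responsibilities_bitwise(self, small_data, small_reference, rng):
        g = small_reference.graph
        theta = np.clip(rng.random((3, small_data.n_genes)), 0.05, 0.95)
        params = HMRFParams(theta=theta, beta=np.zeros(3))
        t0 = Posteriors(t=np.full((small_data.n_voxels, 3), 1 / 3))
        t_hmrf = hc.e_step(small_data, g, params, t0)
        # independent-mixture responsibilities with uniform weights
        le = hmrf.log_emission(small_data, theta)
        le = le - le.max(axis=1, keepdims=True)
        t_mix = np.exp(le)
        t_mix /= t_mix.sum(axis=1, keepdims=True)
        assert np.array_equal(t_hmrf.t, t_mix)

    def test_isolated_voxel_posterior_independent_of_beta(self, rng):
        coords = np.array([[0, 0, 0], [5, 5, 5]])  # two isolated voxels
        g = hc.build_graph(coords)
        y = BinaryExpressionMatrix(y=rng.integers(0, 2, (2, 4)))
        theta = np.clip(rng.random((2, 4)), 0.1, 0.9)
        t0 = Posteriors(t=np.full((2, 2), 0.5))
        t_low = hc.e_step(y, g, HMRFParams(theta=theta, beta=np.zeros(2)), t0)
        t_high = hc.e_step(y, g, HMRFParams(theta=theta, beta=np.array([5.0, 5.0])), t0)
        assert np.allclose(t_low.t, t_high.t)

    def test_three_voxel_line_matches_direct_formula(self, line_graph):
        theta = np.array([[0.9, 0.2], [0.3, 0.8]])
        beta = np.array([1.5, 0.5])
        y = BinaryExpressionMatrix(y=np.array([[1, 0], [1, 1], [0, 1]]))
        t_prev = Posteriors(t=np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]]))
        got = hc.e_step(y, line_graph, HMRFParams(theta=theta, beta=beta), t_prev)
        # brute-force arithmetic of the stated update
        nbrs = {0: [1], 1: [0, 2], 2: [1]}
        for i in range(3):
            w = np.empty(2)
            for k in range(2):
                emis = np.prod(
                    [theta[k, g] if y.y[i, g] else 1 - theta[k, g] for g in range(2)]
                )
                s = sum(t_prev.t[j, k] for j in nbrs[i])
                w[k] = emis * math.exp(beta[k] * s)
            w /= w.sum()
            assert np.allclose(got.t[i], w, atol=1e-12)

    def test_checkerboard_sweep_valid_posteriors(self, small_data, small_reference, rng):
        theta = np.clip(rng.random((3, small_data.n_genes)), 0.1, 0.9)
        params = HMRFParams(theta=theta, beta=np.array([1.0, 0.5, 2.0]))
        t0 = Posteriors(t=np.full((small_data.n_voxels, 3), 1 / 3))
        t = hc.e_step(small_data, small_reference.graph, params, t0, sweep="checkerboard")
        assert np.allclose(t.t.sum(axis=1), 1.0)


class TestMStepTheta:
    def test_half_expressing_cluster_gives_half(self):
        y = BinaryExpressionMatrix(y=np.array([[1], [1], [0], [0]]))
        part = Partition(labels=np.array([1, 1, 1, 1]), n_clusters=1)
        theta = hc.m_step_theta(y, part, 1, clip=False)
        assert theta[0, 0] == pytest.approx(0.5)

    def test_fully_expressing_cluster_is_one_before_clipping(self):
        y = BinaryExpressionMatrix(y=np.ones((3, 2), dtype=int))
        part = Partition(labels=np.array([1, 1, 1]), n_clusters=1)
        assert np.all(hc.m_step_theta(y, part, 1, clip=False) == 1.0)
        assert np.all(hc.m_step_theta(y, part, 1) == 1 - hmrf.THETA_EPS)

    def test_matches_brute_force_counting(self, rng):
        y = BinaryExpressionMatrix(y=rng.integers(0, 2, (20, 5)))
        labels = rng.integers(1, 4, 20)
        part = Partition(labels=labels, n_clusters=3)
        theta = hc.m_step_theta(y, part, 3, clip=False)
        for k in range(1, 4):
            members = labels == k
            if members.any():
                assert np.allclose(theta[k - 1], y.y[members].mean(axis=0))

    def test_relabeling_equivariance(self, rng):
        y = BinaryExpressionMatrix(y=rng.integers(0, 2, (15, 4)))
        labels = rng.integers(1, 4, 15)
        perm = np.array([3, 1, 2])  # new label of old cluster k is perm[k-1]
        relabeled = perm[labels - 1]
        t1 = hc.m_step_theta(y, Partition(labels=labels, n_clusters=3), 3, clip=False)
        t2 = hc.m_step_theta(y, Partition(labels=relabeled, n_clusters=3), 3, clip=False)
        for k in range(3):
            assert np.allclose(t1[k], t2[perm[k] - 1], equal_nan=True)


class TestMStepBeta:
    def test_single_cluster_beta_unchanged(self, line_graph):
        t = Posteriors(t=np.ones((3, 1)))
        beta = hc.m_step_beta(t, line_graph, np.array([0.7]))
        assert beta == pytest.approx([0.7])

    def test_matches_grid_search_on_block_posteriors(self):
        # 2x4x1 grid split into two equal blocks with confident posteriors
        g = hc.build_graph(hc.full_grid_coords((2, 4, 1)))
        t = np.where(g.coords[:, [1]] <= 1, [0.95, 0.05], [0.05, 0.95])
        post = Posteriors(t=t / t.sum(axis=1, keepdims=True))
        fitted = hc.m_step_beta(post, g, np.array([0.1, 0.1]), max_iter=2000, tol=1e-8)
        s = g.adjacency() @ post.t
        grid = np.linspace(0, hmrf.BETA_MAX, 1201)
        best = None
        for b1 in grid:  # coordinate-wise dense scan, two passes
            obj, _ = hmrf._field_objective_and_grad(np.array([b1, fitted[1]]), post.t, s)
            if best is None or obj > best[0]:
                best = (obj, b1)
        assert fitted[0] == pytest.approx(best[1], abs=grid[1] - grid[0] + 1e-2)
        best2 = None
        for b2 in grid:
            obj, _ = hmrf._field_objective_and_grad(np.array([fitted[0], b2]), post.t, s)
            if best2 is None or obj > best2[0]:
                best2 = (obj, b2)
        assert fitted[1] == pytest.approx(best2[1], abs=grid[1] - grid[0] + 1e-2)

    def test_randomized_posteriors_give_near_zero_beta(self, rng):
        g = hc.build_graph(hc.full_grid_coords((6, 6, 3)))
        # posteriors uncorrelated with space: shuffled confident labels
        labels = rng.integers(0, 2, g.n_voxels)
        t = np.where(labels[:, None] == 0, [0.9, 0.1], [0.1, 0.9])
        beta = hc.m_step_beta(Posteriors(t=t), g, np.array([0.1, 0.1]))
        assert np.all(beta < 0.1)

    def test_negative_step_rejected(self, line_graph):
        t = Posteriors(t=np.full((3, 2), 0.5))
        with pytest.raises(ValueError, match="step"):
            hc.m_step_beta(t, line_graph, np.zeros(2), step=-1)


class TestMPM:
    def test_argmax_row(self):
        t = Posteriors(t=np.array([[0.2, 0.8], [0.7, 0.3]]))
        assert list(hc.mpm_assign(t).labels) == [2, 1]

    def test_tie_broken_to_lowest_index(self):
        t = Posteriors(t=np.array([[0.5, 0.5]]))
        assert hc.mpm_assign(t).labels[0] == 1

    def test_matches_brute_force_argmax(self, rng):
        t = rng.random((30, 4))
        t /= t.sum(axis=1, keepdims=True)
        labels = hc.mpm_assign(Posteriors(t=t)).labels
        for i in range(30):
            assert labels[i] == int(np.argmax(t[i])) + 1


class TestFitHMRF:
    def test_k1_theta_equals_global_column_means(self, small_data, small_reference):
        fit = hc.fit_hmrf(small_data, small_reference.graph, 1, seed=0, n_restarts=1)
        assert np.allclose(
            fit.params.theta[0],
            np.clip(small_data.y.mean(axis=0), hmrf.THETA_EPS, 1 - hmrf.THETA_EPS),
        )

    def test_recovers_synthetic_three_cluster_partition(self, small_data, small_reference):
        fit = hc.fit_hmrf(small_data, small_reference.graph, 3, seed=0)
        assert hc.jaccard_partitions(small_reference.partition, fit.partition) > 0.9
        rmse = hc.aligned_theta_rmse(
            small_reference.theta, fit.params.theta, small_reference.partition, fit.partition
        )
        # clusters hold ~40 voxels here, so theta estimates carry binomial
        # sampling noise of ~0.04 per entry even from the exact partition
        assert rmse < 0.1

    def test_trace_non_decreasing_on_returned_fit(self, small_data, small_reference):
        fit = hc.fit_hmrf(small_data, small_reference.graph, 3, seed=0)
        d = np.diff(fit.log_likelihood_trace)
        assert d.size == 0 or d.min() >= -1e-6 * abs(fit.log_likelihood)

    def test_beta_zero_fit_identical_to_uniform_hard_mixture(self, small_data, small_reference):
        fit = hc.fit_hmrf(
            small_data, small_reference.graph, 3, seed=42, n_restarts=1, update_beta=False
        )
        mix = hc.fit_independent_mixture(
            small_data, 3, seed=42, n_restarts=1, weights="uniform", theta_update="hard"
        )
        assert np.array_equal(fit.partition.labels, mix.partition.labels)
        assert np.allclose(fit.posteriors.t, mix.posteriors.t)

    def test_invalid_inputs_rejected(self, small_data, small_reference):
        with pytest.raises(ValueError, match="n_clusters"):
            hc.fit_hmrf(small_data, small_reference.graph, 0)
        with pytest.raises(ValueError, match="exceeds"):
            hc.fit_hmrf(small_data, small_reference.graph, small_data.n_voxels + 1)

    def test_label_permutation_equivariance_of_theta(self, small_data, small_reference):
        # initializing from a relabeled partition permutes theta rows accordingly
        ref = small_reference
        perm = np.array([2, 3, 1])
        relabeled = Partition(labels=perm[ref.partition.labels - 1], n_clusters=3)
        f1 = hc.fit_hmrf(small_data, ref.graph, 3, init=ref.partition, seed=0)
        f2 = hc.fit_hmrf(small_data, ref.graph, 3, init=relabeled, seed=0)
        for k in range(3):
            assert np.allclose(f1.params.theta[k], f2.params.theta[perm[k] - 1], atol=1e-8)


def test_raising_one_beta_never_unsmooths_fixed_pass(small_data, small_reference, rng):
    """On one posterior-update pass from fixed inputs, raising a single
    interaction strength cannot decrease the number of same-label neighbor
    pairs in the resulting MPM partition."""
    g = small_reference.graph
    theta = np.clip(rng.random((3, small_data.n_genes)), 0.2, 0.8)
    t0 = Posteriors(t=np.full((small_data.n_voxels, 3), 1 / 3))
    t0 = hc.e_step(small_data, g, HMRFParams(theta=theta, beta=np.zeros(3)), t0)

    def same_label_pairs(beta_value):
        params = HMRFParams(theta=theta, beta=np.array([0.0, beta_value, 0.0]))
        part = hc.mpm_assign(hc.e_step(small_data, g, params, t0))
        return int(np.sum(part.labels[g.edges[:, 0]] == part.labels[g.edges[:, 1]]))

    counts = [same_label_pairs(b) for b in (0.0, 0.5, 1.0, 2.0, 4.0)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_mean_field_vs_exact_marginals_gap_documented():
    """On a tiny graph the mean-field marginals are compared against exact
    enumeration; the total-variation gap is reported (bounded loosely, not
    asserted tight) to document approximation quality."""
    g = hc.build_graph(hc.full_grid_coords((2, 2, 2)))
    rng = np.random.default_rng(0)
    y = BinaryExpressionMatrix(y=rng.integers(0, 2, (8, 3)))
    theta = np.array([[0.8, 0.2, 0.6], [0.2, 0.7, 0.3]])
    beta = np.array([0.8, 0.8])
    params = HMRFParams(theta=theta, beta=beta)
    # exact posterior marginals by enumeration over 2^8 labelings
    log_em = hmrf.log_emission(y, theta)
    marg = np.zeros((8, 2))
    weights = []
    configs = list(itertools.product((1, 2), repeat=8))
    for cfg in configs:
        part = Partition(labels=np.array(cfg), n_clusters=2)
        lw = -hc.potts_energy(part, g, beta) + sum(log_em[i, cfg[i] - 1] for i in range(8))
        weights.append(lw)
    weights = np.exp(np.array(weights) - max(weights))
    weights /= weights.sum()
    for w, cfg in zip(weights, configs):
        for i, k in enumerate(cfg):
            marg[i, k - 1] += w
    # mean-field fixed point
    t = Posteriors(t=np.full((8, 2), 0.5))
    for _ in range(200):
        t = hc.e_step(y, g, params, t)
    tv_gap = 0.5 * np.abs(t.t - marg).sum(axis=1).max()
    print(f"mean-field vs exact max TV gap: {tv_gap:.4f}")
    assert tv_gap < 0.5  # documented approximation quality, loose bound


def test_e_step_finite_with_boundary_theta(line_graph):
    """theta of exactly 0/1 combined with contradicting observations is
    clipped, never NaN."""
    y = BinaryExpressionMatrix(y=np.array([[1, 0], [0, 1], [1, 1]]))
    params = HMRFParams(theta=np.array([[0.0, 1.0], [1.0, 0.0]]), beta=np.zeros(2))
    t0 = Posteriors(t=np.full((3, 2), 0.5))
    t = hc.e_step(y, line_graph, params, t0)
    assert np.isfinite(t.t).all()
    assert np.allclose(t.t.sum(axis=1), 1.0)
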