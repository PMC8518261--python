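"""Logistic weight transform, midpoint rule, penalty budget, tailored fits."""

import numpy as np
import pytest

from tailored_glasso.core import DataMatrix, empirical_covariance, graph_from_precision
from tailored_glasso.selection import StarsConfig
from tailored_glasso.simulate import generate_scalefree_precision, sample_mvn
from tailored_glasso.solver import solve_glasso
from tailored_glasso.tailored import (
    PriorWeights,
    choose_w0,
    default_k_grid,
    logistic_transform,
    preserve_penalty,
    tailored_fit,
    weighted_glasso_fit,
    weights_from_prior_data,
)


def weights_from_upper(p, entries):
    W = np.zeros((p, p))
    for (i, j), v in entries.items():
        W[i, j] = W[j, i] = v
    return PriorWeights(W)


class TestLogisticTransform:
    def test_k_zero_flattens_everything_to_half(self, rng):
        W = np.abs(rng.uniform(size=(5, 5)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        out = logistic_transform(PriorWeights(np.clip(W, 0, 1)), k=0.0, w0=0.3)
        np.testing.assert_allclose(out, 0.5)

    def test_midpoint_maps_to_half_for_any_k(self):
        for k in (0.0, 1.0, 40.0, 200.0):
            assert logistic_transform(np.array([[0.35]]), k, 0.35)[0, 0] == 0.5

    def test_steep_transform_is_a_step_function(self):
        g = logistic_transform(np.array([[0.4, 0.6]]), k=200.0, w0=0.5)
        assert g[0, 0] < 1e-8
        assert g[0, 1] > 1 - 1e-8

    def test_strictly_increasing_in_weight_for_positive_k(self):
        w = np.linspace(0, 1, 50)[None, :]
        g = logistic_transform(w, k=8.0, w0=0.4)
        assert np.all(np.diff(g[0]) > 0)
        # hence penalties 1 - g are strictly decreasing in prior confidence
        assert np.all(np.diff(1 - g[0]) < 0)

    def test_extreme_steepness_does_not_overflow(self):
        out = logistic_transform(np.array([[0.0, 1.0]]), k=1e6, w0=0.5)
        assert np.isfinite(out).all()

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            logistic_transform(np.zeros((2, 2)), -1.0, 0.5)


class TestChooseW0:
    def test_lower_quantile_of_decile_weights(self):
        entries = {(0, j + 1): (j + 1) / 10 for j in range(10)}
        W = weights_from_upper(12, entries)
        assert choose_w0(W, beta=0.05) == pytest.approx(0.1)

    def test_constant_weights_return_the_constant(self):
        W = weights_from_upper(5, {(0, 1): 0.37, (2, 3): 0.37})
        assert choose_w0(W, beta=0.05) == pytest.approx(0.37)

    def test_beta_one_returns_the_maximum(self):
        entries = {(0, j + 1): (j + 1) / 10 for j in range(10)}
        W = weights_from_upper(12, entries)
        assert choose_w0(W, beta=1.0) == pytest.approx(1.0)

    def test_all_zero_weights_direct_to_unweighted(self):
        with pytest.raises(ValueError, match="unweighted"):
            choose_w0(PriorWeights(np.zeros((4, 4))))


class TestPreservePenalty:
    def test_constant_half_matrix_doubles_lambda(self):
        P = np.full((10, 10), 0.5)
        lam_k = preserve_penalty(0.3, P, 10)
        assert lam_k == pytest.approx(0.6)
        # so lam_k * P is exactly the unweighted penalty lam * 1
        np.testing.assert_allclose(lam_k * P, 0.3)

    def test_all_ones_is_identity(self):
        assert preserve_penalty(0.3, np.ones((7, 7)), 7) == pytest.approx(0.3)

    def test_budget_identity_on_random_matrix(self, rng):
        P = rng.uniform(0.1, 1.0, (4, 4))
        lam_k = preserve_penalty(0.2, P, 4)
        assert lam_k * np.abs(P).sum() == pytest.approx(0.2 * 16, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            preserve_penalty(0.1, np.zeros((3, 3)), 3)


@pytest.fixture(scope="module")
def small_sim():
    """A modest simulated instance with an exact prior, shared across tests."""
    theta, graph = generate_scalefree_precision(40, 0.2, seed=5,
                                                also_feasible_for=0.2)
    data = sample_mvn(theta, 60, seed=6)
    prior_data = sample_mvn(theta, 60, seed=7)
    W = weights_from_prior_data(prior_data, StarsConfig(n_subsamples=6, seed=8))
    return theta, graph, data, W


class TestTailoredFit:
    def test_k_zero_grid_reduces_to_unweighted_glasso(self, small_sim):
        _, _, data, W = small_sim
        lam = 0.4
        res = tailored_fit(data, W, k_grid=[0.0], lambda_=lam,
                           adjust_sparsity=False)
        S = empirical_covariance(data)
        un = solve_glasso(S, lam, validate=False)
        np.testing.assert_allclose(res.theta_hat, un.theta_hat, atol=1e-6)
        assert res.lambda_k == pytest.approx(2 * lam)

    def test_penalty_budget_preserved_on_every_grid_point(self, small_sim):
        _, _, data, W = small_sim
        lam = 0.4
        w0 = choose_w0(W, 0.05)
        p = data.p
        for k in default_k_grid(k_max=80, k_steps=9):
            P_k = 1.0 - logistic_transform(W, float(k), w0)
            lam_k = preserve_penalty(lam, P_k, p)
            assert lam_k * np.abs(P_k).sum() == pytest.approx(lam * p * p, abs=1e-8)

    def test_result_reports_budget_consistent_penalty(self, small_sim):
        _, _, data, W = small_sim
        res = tailored_fit(data, W, k_grid=[0.0, 20.0, 40.0], lambda_=0.4,
                           adjust_sparsity=False)
        budget = res.lambda_k * np.abs(res.penalty_matrix.P).sum()
        assert budget == pytest.approx(res.lambda_ * data.p**2, rel=1e-10)

    def test_k_opt_minimizes_the_reported_path(self, small_sim):
        _, _, data, W = small_sim
        res = tailored_fit(data, W, k_grid=np.linspace(0, 80, 9), lambda_=0.4,
                           adjust_sparsity=False)
        assert res.k_opt == res.k_grid[int(np.argmin(res.ebic_path))]

    def test_sparsity_adjustment_matches_unweighted_edge_count(self, small_sim):
        _, _, data, W = small_sim
        lam = 0.4
        S = empirical_covariance(data)
        target = graph_from_precision(solve_glasso(S, lam, validate=False).theta_hat).n_edges
        res = tailored_fit(data, W, k_grid=np.linspace(0, 80, 9), lambda_=lam,
                           adjust_sparsity=True)
        got = graph_from_precision(res.theta_hat).n_edges
        assert res.target_n_edges == target
        assert abs(got - target) <= 1  # step function: exact or nearest

    def test_empty_k_grid_rejected(self, small_sim):
        _, _, data, W = small_sim
        with pytest.raises(ValueError, match="empty"):
            tailored_fit(data, W, k_grid=[], lambda_=0.4)

    def test_all_zero_prior_rejected_single_entry_accepted(self, small_sim):
        _, _, data, _ = small_sim
        p = data.p
        with pytest.raises(ValueError, match="unweighted"):
            tailored_fit(data, PriorWeights(np.zeros((p, p))), k_grid=[0.0, 10.0],
                         lambda_=0.4)
        W1 = np.zeros((p, p))
        W1[0, 1] = W1[1, 0] = 0.15
        res = tailored_fit(data, PriorWeights(W1), k_grid=[0.0, 10.0], lambda_=0.4,
                           adjust_sparsity=False)
        assert res.w0 == pytest.approx(0.15)

    def test_dimension_mismatch_rejected(self, small_sim):
        _, _, data, _ = small_sim
        with pytest.raises(ValueError, match="p="):
            tailored_fit(data, PriorWeights(np.zeros((3, 3))), lambda_=0.4)

    def test_informative_prior_selects_steeper_transform_than_noise(self, small_sim):
        theta, graph, data, _ = small_sim
        p = data.p
        # perfectly informative weights: 1 on true edges, 0 elsewhere
        W_true = PriorWeights(graph.adjacency())
        # pure-noise weights: same number of entries on random non-edges
        gen = np.random.default_rng(9)
        W_noise = np.zeros((p, p))
        placed = 0
        while placed < graph.n_edges:
            i, j = gen.integers(0, p, 2)
            if i != j and (min(i, j), max(i, j)) not in graph.edges and W_noise[i, j] == 0:
                W_noise[i, j] = W_noise[j, i] = 1.0
                placed += 1
        grid = np.linspace(0, 80, 9)
        k_true = tailored_fit(data, W_true, k_grid=grid, lambda_=0.4,
                              adjust_sparsity=False).k_opt
        k_noise = tailored_fit(data, PriorWeights(W_noise), k_grid=grid,
                               lambda_=0.4, adjust_sparsity=False).k_opt
        assert k_true >= k_noise


class TestWeightsFromPriorData:
    def test_pure_noise_prior_yields_near_empty_weights(self):
        # independent noise has no conditional-dependence signal: the StARS-tuned
        # prior graph is (near) empty and the few spurious weights are tiny
        gen = np.random.default_rng(3)
        noise = DataMatrix(gen.standard_normal((60, 30)))
        W = weights_from_prior_data(noise, StarsConfig(n_subsamples=6, seed=4))
        iu = np.triu_indices(30, 1)
        assert (W.W[iu] > 0).mean() <= 0.03
        assert W.W.max() <= 0.15

    def test_signal_concentrates_on_true_prior_edges(self):
        theta, graph = generate_scalefree_precision(30, 0.2, seed=12)
        prior = sample_mvn(theta, 500, seed=13)
        W = weights_from_prior_data(prior, StarsConfig(n_subsamples=6, seed=14))
        iu = np.triu_indices(30, 1)
        on_edge = np.array([(i, j) in graph.edges for i, j in zip(*iu)])
        assert W.W[iu][on_edge].mean() > 5 * max(W.W[iu][~on_edge].mean(), 1e-6)

    def test_weight_range_matches_weak_signal_regime(self, small_sim):
        # prior partial correlations of 0.2 produce weights in roughly [0, 0.3]
        _, _, _, W = small_sim
        assert 0.0 <= W.W.min() and W.W.max() <= 0.35
        assert np.all(np.diag(W.W) == 0)

    def test_dimension_check(self):
        gen = np.random.default_rng(1)
        noise = DataMatrix(gen.standard_normal((40, 10)))
        with pytest.raises(ValueError, match="expected"):
            weights_from_prior_data(noise, p_expected=12)


class TestWeightedGlasso:
    def test_preservation_rule_applied(self, small_sim):
        _, _, data, W = small_sim
        res, penalty = weighted_glasso_fit(data, W, lambda_=0.4)
        budget = penalty.lam * np.abs(penalty.P).sum()
        assert budget == pytest.approx(0.4 * data.p**2, rel=1e-10)
        assert res.converged
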