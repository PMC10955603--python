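"""Observables: loss expansion, RSMs, NTK oracle, forgetting formula."""

import numpy as np
import pytest

import lindyn as ld
from lindyn.inits import NetworkState
from lindyn.observables import global_minimum, ntk_brute_force
from lindyn.tasks import Dataset, compact_svd

TAU = 2000.0


class TestNetworkFunction:
    def test_identity_network(self):
        qq = ld.QQBlock.from_state(NetworkState(W1=np.eye(3), W2=np.eye(3)))
        np.testing.assert_allclose(ld.network_function(qq), np.eye(3))

    def test_fixed_point_function(self, square_task):
        _, _, svd = square_task
        fp = ld.fixed_point(svd)
        np.testing.assert_allclose(
            ld.network_function(fp), (svd.Utilde * svd.Stilde) @ svd.Vtilde.T,
            atol=1e-12)

    def test_offdiagonal_blocks_are_transposes(self, square_init):
        qq = ld.QQBlock.from_state(square_init)
        Ni = square_init.Ni
        np.testing.assert_allclose(
            qq.M[:Ni, Ni:], ld.network_function(qq).T, atol=1e-12)


class TestLoss:
    def test_minimum_is_zero_for_realisable_task(self):
        data = Dataset(X=np.sqrt(2) * np.eye(2), Y=np.sqrt(2) * np.diag([1.0, 2.0]))
        corr = ld.compute_correlations(data)
        assert ld.loss_from_function(corr.Sigma_yx, corr) == pytest.approx(0.0, abs=1e-14)

    def test_zero_map_pays_mean_square_target(self, square_task):
        _, corr, _ = square_task
        expected = 0.5 * corr.mean_sq_target
        assert ld.loss_from_function(np.zeros_like(corr.Sigma_yx), corr) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_sample_average(self, square_task):
        data, corr, _ = square_task
        rng = np.random.default_rng(3)
        W = rng.standard_normal(corr.Sigma_yx.shape)
        sample = 0.5 * np.mean(np.sum((W @ data.X - data.Y) ** 2, axis=0))
        assert ld.loss_from_function(W, corr) == pytest.approx(sample, abs=1e-12)

    def test_non_whitened_rejected(self):
        corr = ld.compute_correlations(Dataset(X=np.eye(2), Y=np.eye(2)))
        with pytest.raises(ValueError, match="not whitened"):
            ld.loss_from_function(np.eye(2), corr)

    def test_loss_non_increasing_along_analytic_trajectory(
            self, square_task, square_init):
        _, corr, svd = square_task
        times = ld.default_time_grid(svd.Stilde, TAU, n=60)
        traj = ld.exact_qqt(square_init, svd, times, TAU)
        losses = ld.loss_curve(traj, corr)
        assert np.all(np.diff(losses) <= 1e-10)


class TestHiddenRSM:
    def test_identity_input_weights(self):
        qq = ld.QQBlock.from_state(NetworkState(W1=np.eye(3), W2=np.eye(3)))
        rng = np.random.default_rng(5)
        X = rng.standard_normal((3, 4))
        np.testing.assert_allclose(ld.hidden_rsm(qq, X).K, X.T @ X, atol=1e-12)

    def test_sides_agree_for_balanced_states(self):
        rng = np.random.default_rng(6)
        state = ld.random_balanced_init(4, 3, 5, scale=0.8, seed=7)
        qq = ld.QQBlock.from_state(state)
        X = rng.standard_normal((4, 5))
        Ki = ld.hidden_rsm(qq, X, "input-weights").K
        Ko = ld.hidden_rsm(qq, X, "output-weights").K
        np.testing.assert_allclose(Ki, Ko, atol=1e-8)

    def test_fixed_point_rsm_is_task_rsm(self, square_task):
        data, _, svd = square_task
        fp = ld.fixed_point(svd)
        K = ld.hidden_rsm(fp, np.sqrt(data.P) * np.eye(data.Ni)).K
        expected = data.P * (svd.Vtilde * svd.Stilde) @ svd.Vtilde.T
        np.testing.assert_allclose(K, expected, atol=1e-10)


class TestNTK:
    def test_identity_network_kernel(self):
        qq = ld.QQBlock.from_state(NetworkState(W1=np.eye(2), W2=np.eye(2)))
        theta = ld.ntk(qq, np.eye(2)).Theta
        np.testing.assert_allclose(theta, 2 * np.eye(4), atol=1e-12)

    def test_matches_brute_force_jacobian(self):
        rng = np.random.default_rng(8)
        for Ni, No, Nh, P in [(2, 3, 2, 3), (4, 2, 3, 2), (3, 3, 4, 3)]:
            W1 = rng.standard_normal((Nh, Ni))
            W2 = rng.standard_normal((No, Nh))
            X = rng.standard_normal((Ni, P))
            qq = ld.QQBlock.from_state(NetworkState(W1=W1, W2=W2))
            fast = ld.ntk(qq, X).Theta
            slow = ntk_brute_force(W1, W2, X).Theta
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(9)
        state = ld.random_balanced_init(3, 2, 4, scale=1.1, seed=10)
        theta = ld.ntk(ld.QQBlock.from_state(state),
                       rng.standard_normal((3, 4))).Theta
        np.testing.assert_allclose(theta, theta.T, atol=1e-12)
        assert np.linalg.eigvalsh(theta)[0] >= -1e-10 * np.linalg.norm(theta)

    def test_relative_movement_decreases_with_scale_below_task_scale(self):
        # Valid regime: task singular values above every init scale (beyond
        # that the oversized initial function must be unlearned and the
        # ratio turns back up).
        data = ld.make_random_whitened_task(
            3, 3, seed=11, singular_values=(60.0, 40.0, 25.0))
        svd = compact_svd(ld.compute_correlations(data).Sigma_yx)
        from lindyn.experiments import draw_compatible_init
        rng = np.random.default_rng(12)
        movements = []
        for scale in (0.01, 0.1, 1.0, 10.0):
            init = draw_compatible_init(svd, 3, 3, 4, scale, rng)
            T = 50.0 * TAU / svd.Stilde.min()
            traj = ld.exact_qqt(init, svd, np.array([T]), TAU)
            th0 = ld.ntk(ld.QQBlock.from_state(init), data.X).Theta
            thT = ld.ntk(traj.qq_blocks[0], data.X).Theta
            movements.append(np.linalg.norm(thT - th0) / np.linalg.norm(th0))
        assert np.all(np.diff(movements) < 0)


class TestForgetting:
    def test_same_task_costs_only_the_constant(self, square_task):
        _, corr, _ = square_task
        assert ld.forgetting_loss(corr.Sigma_yx, corr) == pytest.approx(
            global_minimum(corr), abs=1e-12)

    def test_orthogonal_rank_one_tasks(self):
        data_i = Dataset(X=np.sqrt(2) * np.eye(2),
                         Y=np.sqrt(2) * np.diag([1.0, 0.0]))
        corr_i = ld.compute_correlations(data_i)
        assert ld.forgetting_loss(np.diag([0.0, 1.0]), corr_i) == pytest.approx(
            1.0 + global_minimum(corr_i), abs=1e-12)

    def test_matches_train_to_convergence(self, square_task):
        _, corr_i, _ = square_task
        data_j = ld.make_random_whitened_task(3, 3, seed=13)
        corr_j = ld.compute_correlations(data_j)
        svd_j = compact_svd(corr_j.Sigma_yx)
        from lindyn.experiments import draw_compatible_init
        init = draw_compatible_init(svd_j, 3, 3, 4, 0.3, np.random.default_rng(14))
        T = 60.0 * TAU / svd_j.Stilde.min()
        traj = ld.exact_qqt(init, svd_j, np.array([T]), TAU)
        trained_loss = ld.loss_from_function(traj.qq_blocks[0].function, corr_i)
        predicted = ld.forgetting_loss(corr_j.Sigma_yx, corr_i)
        assert trained_loss == pytest.approx(predicted, abs=1e-6)

    def test_dimension_mismatch_rejected(self, square_task):
        _, corr, _ = square_task
        with pytest.raises(ValueError, match="shape mismatch"):
            ld.forgetting_loss(np.eye(2), corr)

    def test_matrix_layout(self, square_task):
        _, corr, _ = square_task
        corr2 = ld.compute_correlations(ld.make_random_whitened_task(3, 3, seed=15))
        F = ld.forgetting_matrix([corr, corr2])
        assert F.shape == (2, 2)
        assert F[0, 0] == pytest.approx(global_minimum(corr), abs=1e-12)
        assert F[0, 1] == pytest.approx(
            ld.forgetting_loss(corr.Sigma_yx, corr2), abs=1e-12)
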