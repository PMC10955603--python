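"""Closed-form solvers: continuity, convergence, cross-solver equivalence."""

import numpy as np
import pytest

import lindyn as ld
from lindyn.experiments import draw_compatible_init
from lindyn.riccati import AssumptionViolation, TwoByTwoInit
from lindyn.tasks import compact_svd

TAU = 2000.0  # 1/eta at the reference learning rate 5e-4


class TestFukumizuForm:
    def test_continuous_at_t_zero(self, square_task, square_init):
        _, corr, _ = square_task
        traj = ld.riccati_fukumizu(square_init, corr.Sigma_yx,
                                   np.array([1e-12]), TAU)
        np.testing.assert_allclose(
            traj.qq_blocks[0].M, square_init.qq_matrix(), atol=1e-8)

    def test_agrees_with_stable_form_at_moderate_times(
            self, square_task, square_init):
        _, corr, svd = square_task
        times = np.linspace(0.2 * TAU, 5 * TAU, 12)
        a = ld.riccati_fukumizu(square_init, corr.Sigma_yx, times, TAU)
        b = ld.exact_qqt(square_init, svd, times, TAU)
        dev = max(np.abs(x.M - y.M).max()
                  for x, y in zip(a.qq_blocks, b.qq_blocks))
        assert dev <= 1e-6

    def test_singular_sigma_rejected(self, square_init):
        with pytest.raises(AssumptionViolation, match="full-rank"):
            ld.riccati_fukumizu(square_init, np.diag([1.0, 0.0, 0.0]),
                                np.array([1.0]), TAU)

    def test_nonsquare_sigma_rejected(self, square_init):
        with pytest.raises(AssumptionViolation, match="equal-dimensions"):
            ld.riccati_fukumizu(square_init, np.ones((2, 3)),
                                np.array([1.0]), TAU)


class TestStableGeneralForm:
    def test_continuous_at_t_zero(self, square_task, square_init):
        _, _, svd = square_task
        traj = ld.exact_qqt(square_init, svd, np.array([1e-12]), TAU)
        np.testing.assert_allclose(
            traj.qq_blocks[0].M, square_init.qq_matrix(), atol=1e-8)

    @pytest.mark.parametrize("dims,scale", [((3, 3), 0.3), ((4, 3), 1.0),
                                            ((2, 5), 5.0)])
    def test_converges_to_fixed_point(self, dims, scale):
        Ni, No = dims
        data = ld.make_random_whitened_task(Ni, No, seed=Ni * 10 + No)
        svd = compact_svd(ld.compute_correlations(data).Sigma_yx)
        init = draw_compatible_init(svd, Ni, No, max(Ni, No) + 1, scale,
                                    np.random.default_rng(1))
        T = 50.0 * TAU / svd.Stilde.min()
        traj = ld.exact_qqt(init, svd, np.array([T]), TAU)
        fp = ld.fixed_point(svd)
        assert np.linalg.norm(traj.qq_blocks[0].M - fp.M) <= 1e-6

    def test_blocks_symmetric_psd_along_trajectory(self, square_task, square_init):
        _, _, svd = square_task
        times = ld.default_time_grid(svd.Stilde, TAU, n=40)
        traj = ld.exact_qqt(square_init, svd, times, TAU)
        for qq in traj.qq_blocks:
            assert qq.min_eigenvalue() >= -1e-8 * np.linalg.norm(qq.M)

    def test_distance_to_fixed_point_decreases(self, square_task, square_init):
        _, _, svd = square_task
        times = np.geomspace(0.5 * TAU, 40 * TAU / svd.Stilde.min(), 30)
        traj = ld.exact_qqt(square_init, svd, times, TAU)
        fp = ld.fixed_point(svd)
        dists = [np.linalg.norm(qq.M - fp.M) for qq in traj.qq_blocks]
        assert np.all(np.diff(dists) <= 1e-10)

    def test_singular_B_raises_with_guidance(self, square_task):
        _, corr, svd = square_task
        rev = ld.balanced_init_from_product(-corr.Sigma_yx, 4)
        with pytest.raises(AssumptionViolation, match="perturb_eps"):
            ld.exact_qqt(rev, svd, np.array([1.0]), TAU)


class TestFixedPoint:
    def test_rich_representation_blocks(self):
        data = ld.make_random_whitened_task(2, 2, seed=0,
                                            singular_values=(2.0, 1.0))
        svd = compact_svd(ld.compute_correlations(data).Sigma_yx)
        fp = ld.fixed_point(svd)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(fp.w1t_w1)), [1.0, 2.0], atol=1e-10)
        assert fp.min_eigenvalue() >= -1e-12

    def test_function_attains_global_minimum(self, square_task):
        _, corr, svd = square_task
        fp = ld.fixed_point(svd)
        c = ld.global_minimum(corr)
        assert ld.loss_from_function(fp.function, corr) == pytest.approx(c, abs=1e-12)


class TestAlignedDynamics:
    def test_exact_at_t_zero_and_converges_to_task(self, square_task):
        _, _, svd = square_task
        A0tA0 = np.array([[0.2, 0.05, 0.0], [0.05, 0.1, 0.02], [0.0, 0.02, 0.3]])
        out = ld.aligned_dynamics(A0tA0, svd.Stilde,
                                  np.array([1e-12, 80 * TAU / svd.Stilde.min()]), TAU)
        np.testing.assert_allclose(out[0], A0tA0, atol=1e-10)
        np.testing.assert_allclose(out[1], np.diag(svd.Stilde), atol=1e-8)

    def test_lift_matches_general_solution(self, square_task):
        _, _, svd = square_task
        rng = np.random.default_rng(6)
        A0 = 0.4 * rng.standard_normal((3, 3))
        init = ld.aligned_init(A0, svd)
        times = np.geomspace(0.1 * TAU, 20 * TAU, 25)
        lifted = ld.lift_aligned(
            ld.aligned_dynamics(A0.T @ A0, svd.Stilde, times, TAU),
            svd, times, TAU)
        general = ld.exact_qqt(init, svd, times, TAU)
        dev = max(np.abs(a.M - b.M).max()
                  for a, b in zip(lifted.qq_blocks, general.qq_blocks))
        assert dev <= 1e-8

    def test_singular_gram_rejected(self):
        with pytest.raises(AssumptionViolation, match="singular"):
            ld.aligned_dynamics(np.diag([1.0, 0.0]), np.array([1.0, 1.0]),
                                np.array([1.0]), TAU)


class TestTwoByTwoPeak:
    def test_printed_formula_value(self):
        init2 = TwoByTwoInit(a1=0.1, a2=0.1, b0=0.05, s1=1.0, s2=1.0)
        t_peak = ld.two_by_two_offdiag_peak(init2, tau=1.0)
        assert t_peak == pytest.approx(0.25 * np.log(0.8 / 0.0075), rel=1e-12)

    def test_decoupled_init_has_no_peak(self):
        init2 = TwoByTwoInit(a1=0.1, a2=0.2, b0=0.0, s1=1.0, s2=1.0)
        assert ld.two_by_two_offdiag_peak(init2, tau=1.0) is None

    def test_large_init_has_no_peak(self):
        init2 = TwoByTwoInit(a1=0.6, a2=0.6, b0=0.1, s1=1.0, s2=1.0)
        assert ld.two_by_two_offdiag_peak(init2, tau=1.0) is None

    def test_matches_grid_argmax_in_small_init_regime(self):
        init2 = TwoByTwoInit(a1=0.02, a2=0.03, b0=0.015, s1=1.0, s2=1.0)
        tau = 1.0
        t_peak = ld.two_by_two_offdiag_peak(init2, tau)
        grid = np.linspace(1e-4, 8.0, 3000)
        atats = ld.aligned_dynamics(init2.gram, np.array([1.0, 1.0]), grid, tau)
        b_abs = [abs(A[0, 1]) for A in atats]
        assert abs(t_peak - grid[np.argmax(b_abs)]) <= grid[1] - grid[0]

    def test_unequal_singular_values_rejected(self):
        init2 = TwoByTwoInit(a1=0.1, a2=0.1, b0=0.05, s1=2.0, s2=1.0)
        with pytest.raises(AssumptionViolation, match="equal singular values"):
            ld.two_by_two_offdiag_peak(init2, tau=1.0)


class TestSigmoidMode:
    def test_initial_and_asymptotic_values(self):
        times = np.array([0.0, 1e4])
        out = ld.sigmoid_mode(0.02, 0.0, s=1.5, times=times, tau=1.0)
        assert out[0] == pytest.approx(0.02, abs=1e-14)
        assert out[1] == pytest.approx(1.5, abs=1e-8)

    def test_matches_rank_one_aligned_dynamics(self):
        s, tau, a0 = 1.0, 1.0, 0.01
        b0 = a0 * (1 - 1e-6)
        times = np.linspace(1e-3, 5.0, 500)
        sig = ld.sigmoid_mode(a0, a0, s, times, tau)
        atats = ld.aligned_dynamics(np.array([[a0, b0], [b0, a0]]),
                                    np.array([s, s]), times, tau)
        a11 = np.array([A[0, 0] for A in atats])
        assert np.abs(sig - a11).max() <= 1e-3


class TestShallowDynamics:
    def test_endpoints(self, square_task):
        _, corr, _ = square_task
        W0 = -corr.Sigma_yx
        out = ld.shallow_dynamics(W0, corr.Sigma_yx, np.array([1e-12, 30 * TAU]), TAU)
        np.testing.assert_allclose(out[0], W0, atol=1e-10)
        np.testing.assert_allclose(out[1], corr.Sigma_yx, atol=1e-8)

    def test_matches_single_layer_gradient_descent(self):
        data = ld.make_random_whitened_task(2, 2, seed=8,
                                            singular_values=(0.6, 0.4))
        corr = ld.compute_correlations(data)
        eta = 1e-3
        W = np.zeros_like(corr.Sigma_yx)
        steps = 3000
        snap, times = [], []
        for k in range(1, steps + 1):
            W = W - eta * (W @ corr.Sigma_xx - corr.Sigma_yx)
            if k % 100 == 0:
                snap.append(W.copy())
                times.append(float(k))
        exact = ld.shallow_dynamics(np.zeros_like(W), corr.Sigma_yx,
                                    np.array(times), tau=1.0 / eta)
        dev = max(np.abs(a - b).max() for a, b in zip(snap, exact))
        assert dev <= 1e-4


class TestFactorQQt:
    def test_fixed_point_roundtrip(self, square_task):
        _, _, svd = square_task
        fp = ld.fixed_point(svd)
        state = ld.factor_qqt(fp, Nh=4, seed=2)
        np.testing.assert_allclose(state.product, fp.function, atol=1e-8)
        assert ld.balancedness_gap(state) <= 1e-8
        np.testing.assert_allclose(state.qq_matrix(), fp.M, atol=1e-8)

    def test_mid_trajectory_roundtrip(self, square_task, square_init):
        _, _, svd = square_task
        traj = ld.exact_qqt(square_init, svd, np.array([2.0 * TAU]), TAU)
        qq = traj.qq_blocks[0]
        state = ld.factor_qqt(qq, Nh=5, seed=3)
        np.testing.assert_allclose(state.qq_matrix(), qq.M, atol=1e-8)

    def test_non_psd_rejected(self):
        qq = ld.QQBlock(M=np.diag([1.0, 1.0, -0.5, 1.0]), Ni=2, No=2)
        with pytest.raises(ValueError, match="positive semidefinite"):
            ld.factor_qqt(qq, 3)

    def test_zero_function_gives_zero_state(self):
        qq = ld.QQBlock(M=np.zeros((4, 4)), Ni=2, No=2)
        state = ld.factor_qqt(qq, Nh=3)
        assert np.all(state.W1 == 0) and np.all(state.W2 == 0)
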