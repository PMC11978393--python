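"""Fused graphical lasso ADMM: closed forms, fixed points, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdeeg import GroupedSamples
from hdeeg.fgl_admm import (
    AdmmState,
    FglHyper,
    FglProblem,
    admm_step,
    assemble_y,
    empirical_covariances,
    fgl_objective,
    fit_fgl,
    initial_state,
    soft_threshold,
    update_theta,
)
from hdeeg.simulate import gen_scenario

from .conftest import scenario_problem
from .oracles import solve_fgl_oracle


def random_problem(rng, p=4, G=2, n=20):
    covs = []
    for _ in range(G):
        A = rng.standard_normal((n, p))
        S = A.T @ A / n
        covs.append(0.5 * (S + S.T))
    return FglProblem(covs, [n] * G)


class TestEmpiricalCovariances:
    def test_identical_rows_give_zero(self):
        gs = GroupedSamples([np.tile([1.0, -2.0], (4, 1))])
        prob = empirical_covariances(gs)
        assert np.allclose(prob.covariances[0], 0.0)

    def test_toy_hand_computation(self):
        gs = GroupedSamples([np.array([[1.0, 0.0], [-1.0, 0.0]])])
        prob = empirical_covariances(gs)
        assert np.allclose(prob.covariances[0], [[1.0, 0.0], [0.0, 0.0]])

    def test_shapes_and_centering(self, rng):
        gs = GroupedSamples([rng.standard_normal((9, 5)) + 7.0])
        prob = empirical_covariances(gs)
        assert prob.covariances[0].shape == (5, 5)
        # group-mean centering removes the large offset
        assert np.abs(prob.covariances[0]).max() < 5.0


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z, alpha, expected",
        [(1.2, 0.5, 0.7), (-1.2, 0.5, -0.7), (0.3, 0.5, 0.0), (0.5, 0.5, 0.0)],
    )
    def test_scalar_branches(self, z, alpha, expected):
        assert soft_threshold(z, alpha) == pytest.approx(expected)

    def test_offdiag_passes_diagonal_through(self):
        M = np.array([[5.0, 1.2], [-1.2, -3.0]])
        out = soft_threshold(M, 0.5, offdiag=True)
        assert out[0, 0] == 5.0 and out[1, 1] == -3.0
        assert out[0, 1] == pytest.approx(0.7)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0, 3))
    def test_contraction(self, a, b, alpha):
        fa, fb = soft_threshold(a, alpha), soft_threshold(b, alpha)
        assert abs(fa - fb) <= abs(a - b) + 1e-12


class TestAssembleY:
    def test_single_group_has_no_fusion_terms(self, rng):
        prob = random_problem(rng, G=1)
        state = initial_state(prob, init="zeros")
        state.Z = [np.zeros((4, 4))]
        Y = assemble_y(0, state, prob, FglHyper())
        assert np.allclose(Y, prob.covariances[0])

    def test_two_groups_zero_arguments_reduce_to_s(self, rng):
        prob = random_problem(rng, G=2)
        z = np.zeros((4, 4))
        state = AdmmState(
            Theta=[z.copy(), z.copy()], Z=[z.copy(), z.copy()],
            Delta=[z.copy()], V=[z.copy(), z.copy()], U=[z.copy()],
        )
        Y = assemble_y(0, state, prob, FglHyper())
        assert np.allclose(Y, prob.covariances[0])

    def test_middle_group_has_opposite_sign_fusion_terms(self, rng):
        prob = random_problem(rng, G=3)
        z = np.zeros((4, 4))
        U0 = np.full((4, 4), 0.5)
        U1 = np.full((4, 4), 0.25)
        state = AdmmState(
            Theta=[z.copy()] * 3, Z=[z.copy()] * 3,
            Delta=[z.copy(), z.copy()], V=[z.copy()] * 3, U=[U0, U1],
        )
        Y = assemble_y(1, state, prob, FglHyper(rho2=2.0))
        expected = prob.covariances[1] - 2.0 * U0 + 2.0 * U1
        assert np.allclose(Y, expected)

    def test_index_out_of_range(self, rng):
        prob = random_problem(rng, G=2)
        state = initial_state(prob)
        with pytest.raises(IndexError):
            assemble_y(2, state, prob, FglHyper())


class TestUpdateTheta:
    def test_zero_input_gives_identity(self):
        assert np.allclose(update_theta(np.zeros((3, 3)), 1.0), np.eye(3))

    def test_diagonal_eigenvalue_map(self):
        out = update_theta(np.diag([2.0, -2.0]), 1.0)
        assert np.allclose(np.diag(out), [(-2 + np.sqrt(8)) / 2, (2 + np.sqrt(8)) / 2])

    def test_stationarity_identity(self, rng):
        Y = rng.standard_normal((5, 5))
        Y = 0.5 * (Y + Y.T)
        rho = 1.7
        T = update_theta(Y, rho)
        assert np.abs(rho * T @ T + Y @ T - np.eye(5)).max() < 1e-8

    def test_output_positive_definite(self, rng):
        Y = rng.standard_normal((6, 6)) * 10
        Y = 0.5 * (Y + Y.T)
        T = update_theta(Y, 0.5)
        assert np.linalg.eigvalsh(T)[0] > 0


class TestAdmmStep:
    def test_large_lambda1_zeroes_slack_offdiagonals(self, rng):
        prob = random_problem(rng)
        state = initial_state(prob)
        admm_step(state, prob, FglHyper(lambda1=1e6, lambda2=0.1))
        for Z in state.Z:
            off = Z - np.diag(np.diag(Z))
            assert np.abs(off).max() == 0.0

    def test_iterates_stay_positive_definite(self, rng):
        prob = random_problem(rng, p=5)
        state = initial_state(prob)
        hyper = FglHyper(0.2, 0.2)
        for _ in range(30):
            admm_step(state, prob, hyper)
            for T in state.Theta:
                assert np.linalg.eigvalsh(T)[0] > 0

    def test_near_fixed_point_is_stable(self, rng):
        # from a converged solution, one more sweep moves Theta negligibly
        prob = random_problem(rng)
        hyper = FglHyper(0.1, 0.1)
        fit = fit_fgl(prob, hyper, max_iter=2000, epsilon=1e-13)
        state = initial_state(prob)
        for _ in range(2000):
            admm_step(state, prob, hyper)
        before = [T.copy() for T in state.Theta]
        admm_step(state, prob, hyper)
        drift = max(np.abs(T - B).max() for T, B in zip(state.Theta, before))
        assert drift < 1e-10


class TestFitFgl:
    def test_unpenalized_single_group_recovers_inverse(self, rng):
        prob = random_problem(rng, G=1)
        fit = fit_fgl(prob, FglHyper(0.0, 0.0))
        err = np.linalg.norm(fit.Theta_hat[0] - np.linalg.inv(prob.covariances[0]))
        assert err < 1e-4

    @pytest.mark.parametrize("p", [4, 6])
    @pytest.mark.parametrize("lams", [(0.1, 0.1), (0.05, 0.3), (0.3, 0.05)])
    def test_matches_proximal_gradient_oracle(self, rng, p, lams):
        prob = random_problem(rng, p=p)
        l1, l2 = lams
        fit = fit_fgl(prob, FglHyper(l1, l2))
        ours = fgl_objective(fit.Theta_hat, prob, l1, l2)
        _, oracle = solve_fgl_oracle(prob.covariances, l1, l2)
        assert abs(ours - oracle) < 1e-3

    def test_huge_fusion_penalty_fuses_offdiagonals(self, rng):
        prob = random_problem(rng)
        fit = fit_fgl(prob, FglHyper(0.05, 100.0))
        d = fit.Theta_hat[0] - fit.Theta_hat[1]
        d -= np.diag(np.diag(d))
        assert np.abs(d).max() < 1e-4

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        prob = random_problem(rng)
        fit = fit_fgl(prob, FglHyper(0.1, 0.1), max_iter=2, epsilon=1e-15)
        assert not fit.converged and fit.iterations == 2

    def test_zero_dual_init_reaches_same_solution(self, rng):
        prob = random_problem(rng)
        f1 = fit_fgl(prob, FglHyper(0.1, 0.1), init="paper")
        f2 = fit_fgl(prob, FglHyper(0.1, 0.1), init="zeros")
        assert np.abs(f1.Theta_hat[0] - f2.Theta_hat[0]).max() < 1e-5

    def test_scenario_instances_converge_below_1e6(self):
        # relative l1 change drops below 1e-6 within 500 sweeps
        for scenario in ("I", "V"):
            prob, _ = scenario_problem(scenario, np.random.default_rng(3))
            fit = fit_fgl(
                prob, FglHyper(0.1, 0.1), max_iter=500, epsilon=1e-6,
                record_objective=False,
            )
            assert fit.relative_change <= 1e-6


class TestFglObjective:
    def test_identity_case(self):
        prob = FglProblem([np.eye(3), np.eye(3)], [10, 10])
        val = fgl_objective([np.eye(3), np.eye(3)], prob, 0.0, 0.0)
        assert val == pytest.approx(2 * 3)

    def test_l1_term_ignores_zero_offdiagonals(self):
        prob = FglProblem([np.eye(3)], [10])
        base = fgl_objective([2.0 * np.eye(3)], prob, 0.0, 0.0)
        with_l1 = fgl_objective([2.0 * np.eye(3)], prob, 1.0, 0.0)
        assert with_l1 == pytest.approx(base)

    def test_identical_groups_have_zero_fusion_term(self, rng):
        prob = random_problem(rng, G=2)
        T = np.eye(4) + 0.1
        a = fgl_objective([T, T], prob, 0.0, 0.0)
        b = fgl_objective([T, T], prob, 0.0, 50.0)
        assert a == pytest.approx(b)

    def test_non_pd_input_raises(self):
        prob = FglProblem([np.eye(2)], [5])
        with pytest.raises(ValueError, match="positive definite"):
            fgl_objective([np.diag([1.0, -1.0])], prob, 0.0, 0.0)


def test_fusion_pair_count_vs_admm_chain():
    """The objective fuses all G(G-1)/2 pairs; the ADMM chains G-1 adjacent
    constraints. They coincide for G = 2 (the standard two-epoch use)."""
    rng = np.random.default_rng(0)
    prob = random_problem(rng, G=4)
    state = initial_state(prob)
    assert len(state.Delta) == prob.G - 1 == 3
    G = prob.G
    assert G * (G - 1) // 2 == 6  # objective pairs, documented discrepancy
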