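"""Equilibria: linear solves, Jacobians, stability reports, subset sampling."""

import numpy as np
import pytest

import glvec as g
from glvec.ensembles import ConfigurationError
from glvec.equilibria import (
    DegenerateEquilibriumError,
    community_from_subset,
    enumerate_stable_subsets,
)


def uniform_matrix(n, a):
    A = np.full((n, n), float(a))
    np.fill_diagonal(A, 0.0)
    return A


class TestSolveEquilibrium:
    def test_empty_interactions_give_unit_abundances(self):
        assert np.allclose(g.solve_equilibrium(np.zeros((4, 4))), 1.0)

    def test_two_species_hand_solution(self):
        # (I - A) x = 1 with A12=-0.3, A21=-0.6: x = (0.7, 0.4)/0.82
        A = np.array([[0.0, -0.3], [-0.6, 0.0]])
        x = g.solve_equilibrium(A)
        assert x == pytest.approx([0.7 / 0.82, 0.4 / 0.82])

    def test_singular_system_raises(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(DegenerateEquilibriumError):
            g.solve_equilibrium(A)

    def test_equilibrium_is_growth_rate_independent(self):
        # x* solves a linear system that never involves r.
        A = uniform_matrix(5, -0.3)
        x = g.solve_equilibrium(A)
        assert np.allclose(x, 1.0 / (1.0 + 4 * 0.3))


class TestFeasibility:
    def test_exclusionary_pair_is_infeasible(self):
        feas, x = g.is_feasible(np.array([[0.0, -1.5], [-0.2, 0.0]]))
        assert not feas
        assert (x <= 0).any()

    def test_rps_triplet_is_feasible(self):
        A = uniform_matrix(3, -0.2)
        A[1, 0] = A[2, 1] = A[0, 2] = -1.5
        feas, x = g.is_feasible(A)
        assert feas
        assert np.allclose(x, np.linalg.solve(np.eye(3) - A, np.ones(3)))


class TestJacobian:
    def test_identity_case(self):
        J = g.jacobian(np.zeros((3, 3)), np.ones(3))
        assert np.array_equal(J, -np.eye(3))

    def test_symmetric_pair_spectrum(self):
        # a = -0.5, x* = 2/3: J = (2/3) [[-1,-.5],[-.5,-1]], eig -1/3, -1
        A = uniform_matrix(2, -0.5)
        x = g.solve_equilibrium(A)
        assert np.allclose(x, 2.0 / 3.0)
        J = g.jacobian(A, x)
        eig = np.sort(np.linalg.eigvals(J).real)
        assert eig == pytest.approx([-1.0, -1.0 / 3.0])

    def test_growth_rates_scale_but_do_not_destabilize(self):
        A = uniform_matrix(3, -0.4)
        x = g.solve_equilibrium(A)
        J1 = g.jacobian(A, x)
        J2 = g.jacobian(A, x, r_star=2 * np.ones(3))
        assert np.allclose(J2, 2 * J1)
        assert g.is_linearly_stable(J1).stable == g.is_linearly_stable(J2).stable


class TestStabilityReport:
    def test_negative_identity_routh_hurwitz(self):
        rep = g.is_linearly_stable(-np.eye(3))
        assert rep.stable and not rep.marginal
        # (lambda+1)^3: C = (3, 3, 1), Lambda2 = 3*3 - 1 = 8
        assert rep.char_coeffs == pytest.approx([3.0, 3.0, 1.0])
        assert rep.lambda2 == pytest.approx(8.0)

    def test_positive_identity_unstable(self):
        rep = g.is_linearly_stable(np.eye(3))
        assert not rep.stable
        assert rep.lambda2 == pytest.approx((-3.0) * 3.0 - (-1.0))

    def test_marginal_spectrum_rejected(self):
        J = np.diag([-1.0, -1.0, -1e-12])
        rep = g.is_linearly_stable(J)
        assert rep.marginal and not rep.stable

    def test_may_fields_attached_when_stats_given(self):
        rep = g.is_linearly_stable(-np.eye(4), mu_star=-0.9, sigma_star=0.5)
        assert rep.may_mu_c == pytest.approx(np.sqrt(2.0) * 0.5 - 1.0)
        assert rep.violates_may is True  # -0.9 < mu_c ~ -0.29


class TestMayThreshold:
    def test_zero_heterogeneity_reduces_to_self_regulation(self):
        assert g.may_threshold(10, 0.0) == pytest.approx(-1.0)
        assert g.may_threshold(10, 0.0, reading="printed") == pytest.approx(-1.0)

    def test_threshold_rises_with_diversity_and_heterogeneity(self):
        assert g.may_threshold(20, 0.5) > g.may_threshold(10, 0.5)
        assert g.may_threshold(10, 0.8) > g.may_threshold(10, 0.5)

    def test_stable_communities_below_threshold_exist(self, grid_communities):
        # Moderate-size communities routinely stay stable beyond the
        # large-community random-matrix limit.
        violations = 0
        for c, _, _ in grid_communities:
            if c.S_star >= 4 and c.mu_star < g.may_threshold(c.S_star, c.sigma_star):
                violations += 1
        assert violations > 0


class TestSubsetSampling:
    def test_weak_uniform_competition_always_accepted(self):
        A = uniform_matrix(10, -0.2)
        m = g.InteractionMatrix(A=A, r=np.ones(10), K=np.ones(10))
        comms = g.sample_stable_subsets(m, [3], 25, seed=0)
        assert len(comms) == 25
        for c in comms:
            assert np.allclose(c.x_star, 1.0 / 1.4)

    def test_strong_uniform_competition_never_accepted(self):
        A = uniform_matrix(10, -1.5)
        m = g.InteractionMatrix(A=A, r=np.ones(10), K=np.ones(10))
        assert g.sample_stable_subsets(m, [3], 50, seed=0) == []

    def test_zero_samples_empty(self, small_pool):
        assert g.sample_stable_subsets(small_pool, [3], 0, seed=0) == []

    def test_size_out_of_range_rejected(self, small_pool):
        with pytest.raises(ConfigurationError):
            g.sample_stable_subsets(small_pool, [9], 5, seed=0)

    def test_measured_statistics_match_submatrix(self, small_pool):
        comms = g.sample_stable_subsets(small_pool, [3, 4], 200, seed=1)
        assert comms
        for c in comms:
            off = c.A_star[~np.eye(c.S_star, dtype=bool)]
            assert c.mu_star == pytest.approx(off.mean())
            assert c.sigma_star == pytest.approx(off.std())

    def test_sampled_subsets_agree_with_enumeration(self, small_pool):
        # Every subset the sampler accepts appears in the brute-force list,
        # and sampling densely enough recovers a subset of it.
        exhaustive = {
            tuple(c.pool_indices) for c in enumerate_stable_subsets(small_pool)
        }
        sampled = g.sample_stable_subsets(small_pool, [2, 3, 4, 5], 300, seed=3)
        assert sampled
        for c in sampled:
            assert tuple(c.pool_indices) in exhaustive

    def test_routh_hurwitz_holds_for_all_accepted(self, grid_communities):
        # Stability implies the second Routh-Hurwitz condition for S* >= 3.
        checked = 0
        for c, _, _ in grid_communities:
            if c.S_star < 3:
                continue
            rep = g.is_linearly_stable(g.jacobian(c.A_star, c.x_star, c.r_star))
            assert rep.lambda2 > 0
            checked += 1
        assert checked >= 1000


class TestDynamicsSamplingAgreement:
    def test_dynamics_survivors_are_stable_subsets(self, small_pool):
        # Survivor sets found by integrating the dynamics are among the
        # feasible+stable subsets found by exhaustive enumeration.
        exhaustive = {
            tuple(c.pool_indices) for c in enumerate_stable_subsets(small_pool)
        }
        rng = np.random.default_rng(0)
        found = 0
        for _ in range(10):
            traj = g.integrate_glv(small_pool, rng.uniform(0, 1, 8), t1=800, t2=50)
            if traj.status != "stationary":
                continue
            c = g.surviving_community(traj, small_pool)
            assert tuple(c.pool_indices) in exhaustive
            found += 1
        assert found >= 5
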