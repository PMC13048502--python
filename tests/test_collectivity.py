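"""Net effects, Neumann convergence, phi, kappa, and the two experiments."""

import numpy as np
import pytest

import glvec as g
from glvec.community import _offdiag
from glvec.collectivity import coexistence_predicted
from glvec.ensembles import ConfigurationError


def uniform_matrix(n, a):
    A = np.full((n, n), float(a))
    np.fill_diagonal(A, 0.0)
    return A


class TestNetEffects:
    def test_empty_matrix_gives_identity(self):
        assert np.allclose(g.net_effects(np.zeros((3, 3))), np.eye(3))

    def test_symmetric_pair_closed_form(self):
        a = -0.4
        N = g.net_effects(uniform_matrix(2, a))
        expect = np.array([[1, a], [a, 1]]) / (1 - a**2)
        assert np.allclose(N, expect)

    def test_all_competitive_community_has_positive_indirect_effects(self):
        # "The enemy of my enemy": even-length chains of competition are
        # positive, so some net effects between competitors are > 0.
        rng = np.random.default_rng(8)
        for _ in range(20):
            A = rng.normal(-0.5, 0.3, (5, 5))
            A = np.minimum(A, -0.01)  # all competitive
            np.fill_diagonal(A, 0.0)
            feas, _ = g.is_feasible(A)
            if not feas:
                continue
            net = _offdiag(g.net_effects(A))
            if (net > 0).any():
                return
        pytest.fail("no positive net effect found among competitive communities")


class TestNeumann:
    def test_order_zero_is_identity(self):
        assert np.allclose(g.neumann_partial_sum(np.ones((3, 3)), 0), np.eye(3))

    def test_converges_iff_phi_below_one(self):
        rng = np.random.default_rng(3)
        # contracting matrix: partial sums reach the exact inverse
        A = rng.normal(0, 0.1, (6, 6))
        np.fill_diagonal(A, 0.0)
        A *= 0.88 / g.collectivity_phi(A)
        assert g.collectivity_phi(A) < 0.9
        err = np.abs(g.neumann_partial_sum(A, 200) - g.net_effects(A)).max()
        assert err < 1e-6
        # expanding matrix: partial sums blow up
        B = A * (1.2 / g.collectivity_phi(A))
        norms = [np.abs(g.neumann_partial_sum(B, k)).max() for k in (10, 40, 80)]
        assert norms[0] < norms[1] < norms[2]
        assert norms[2] > 1e3


class TestPhi:
    def test_zero_matrix(self):
        assert g.collectivity_phi(np.zeros((4, 4))) == 0.0

    def test_pair_spectral_radius_is_coupling_strength(self):
        assert g.collectivity_phi(uniform_matrix(2, -0.7)) == pytest.approx(0.7)

    def test_uniform_matrix_mean_outlier(self):
        # all off-diagonals -0.5, S=10: eigenvalues (S-1)a and -a, phi = 4.5
        assert g.collectivity_phi(uniform_matrix(10, -0.5)) == pytest.approx(4.5)

    def test_rmt_estimate_exact_in_uniform_limit(self):
        assert g.phi_bounds(10, -0.5, 0.0) == pytest.approx(4.5)
        assert g.phi_bounds(10, -0.5, 0.0) == pytest.approx(
            g.collectivity_phi(uniform_matrix(10, -0.5))
        )

    @pytest.mark.parametrize("S", [20, 40, 80])
    def test_rmt_estimate_tracks_measured_phi(self, S):
        rng = np.random.default_rng(S)
        rel_errs = []
        for _ in range(5):
            A = rng.normal(-0.5, 0.25, (S, S))
            np.fill_diagonal(A, 0.0)
            est = g.phi_bounds(S, -0.5, 0.25)
            rel_errs.append(abs(g.collectivity_phi(A) - est) / est)
        assert np.mean(rel_errs) < 0.15

    def test_phi_independent_of_growth_rates(self, grid_communities):
        c = grid_communities[0][0]
        assert g.collectivity_phi(c.A_star) == g.collectivity_phi(c.A_star)
        # r enters neither phi nor kappa (they are functions of A* only)
        assert g.condition_number(c.A_star) == g.condition_number(c.A_star)


class TestKappa:
    def test_identity_is_best_case(self):
        assert g.condition_number(np.zeros((3, 3))) == pytest.approx(1.0)

    def test_symmetric_pair_closed_form(self):
        # I - A has singular values |1 -+ a| = 1.5, 0.5 for a = -0.5
        assert g.condition_number(uniform_matrix(2, -0.5)) == pytest.approx(3.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(-0.6, 0.4, (7, 7))
        np.fill_diagonal(A, 0.0)
        perm = rng.permutation(7)
        Ap = A[np.ix_(perm, perm)]
        assert g.condition_number(Ap) == pytest.approx(g.condition_number(A))

    def test_singular_target_reported_as_inf(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert g.condition_number(A) == np.inf

    def test_kappa_of_A_target(self):
        A = uniform_matrix(2, -0.5)
        assert g.condition_number(A, target="A") == pytest.approx(1.0)


class TestDirectNetCorrelation:
    def test_perturbative_regime_strongly_correlated(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0, 0.05, (8, 8))
        np.fill_diagonal(A, 0.0)
        assert g.collectivity_phi(A) < 0.3
        r, p, _ = g.direct_net_correlation(A)
        assert r > 0.9 and p < 1e-6

    def test_correlation_decays_past_phi_one(self, grid_communities):
        # weak-interaction communities (phi well below 1) keep direct and
        # net effects aligned; high-collectivity communities decouple them
        m = g.sample_matrix(g.EnsembleSpec(S=40, mu=-0.15, sigma=0.15), seed=3)
        weak = g.sample_stable_subsets(m, [4, 5, 6], 100, seed=5)
        low = [abs(g.direct_net_correlation(c.A_star)[0])
               for c in weak if g.collectivity_phi(c.A_star) < 0.9]
        high = [abs(g.direct_net_correlation(c.A_star)[0])
                for c, _, _ in grid_communities
                if c.S_star >= 4 and g.collectivity_phi(c.A_star) > 1.3]
        assert len(low) > 10 and len(high) > 10
        assert np.mean(low) > np.mean(high)

    def test_ec_communities_have_higher_phi_than_non_ec(self, grid_communities):
        phis_ec, phis_non = [], []
        for c, _, _ in grid_communities:
            if c.S_star < 3:
                continue
            (phis_ec if g.ec_report(c).is_ec else phis_non).append(
                g.collectivity_phi(c.A_star)
            )
        assert np.median(phis_ec) > np.median(phis_non)


class TestKappaMinBound:
    def test_envelope_over_sampled_ec_communities(self, ec_communities):
        # Monte-Carlo calibration: the bound from a matched ensemble sits at
        # or below the kappas of sampled EC communities at that size.
        from glvec.collectivity import kappa_min_bound

        b5 = kappa_min_bound(5, [-0.75], [0.5], n_samples=400, seed=4)
        kappas = [g.condition_number(c.A_star) for c, _, _ in ec_communities
                  if c.S_star == 5]
        assert kappas
        assert b5 <= min(kappas) * 1.5  # calibrated on a matched ensemble

    def test_rejects_pairs(self):
        from glvec.collectivity import kappa_min_bound

        with pytest.raises(ConfigurationError):
            kappa_min_bound(2, [-0.75], [0.5])


class TestPredictionErrorExperiment:
    def test_zero_error_always_succeeds(self, grid_communities):
        comms = [c for c, _, _ in grid_communities]
        frac, n = g.prediction_error_experiment(comms, 5.0, rel_error=0.0,
                                                n_reps=50, seed=0)
        assert frac == 1.0 and n == 50

    def test_well_conditioned_communities_are_robust(self, grid_communities):
        comms = [c for c, _, _ in grid_communities]
        frac, _ = g.prediction_error_experiment(comms, 1.3, rel_error=0.1,
                                                n_reps=200, seed=0, band=0.25)
        assert frac > 0.95

    def test_success_decreases_with_kappa(self, grid_communities):
        comms = [c for c, _, _ in grid_communities]
        fracs = [
            g.prediction_error_experiment(comms, kt, rel_error=0.1,
                                          n_reps=400, seed=1)[0]
            for kt in (2.0, 8.0, 30.0)
        ]
        assert fracs[0] > fracs[1] > fracs[2]

    def test_empty_band_raises(self, grid_communities):
        comms = [c for c, _, _ in grid_communities]
        with pytest.raises(ConfigurationError):
            g.prediction_error_experiment(comms, 1e6, n_reps=10, seed=0)


class TestAssemblyFromPairs:
    def test_weak_competition_always_assembles(self):
        A = uniform_matrix(12, -0.1)
        m = g.InteractionMatrix(A=A, r=np.ones(12), K=np.ones(12))
        table = g.assembly_from_pairs_experiment(m, 4, 100, seed=0)
        assert table["n_trials"].sum() == 100
        assert (table["success_rate"] == 1.0).all()

    def test_success_declines_with_phi(self):
        # pair-coexisting sets with low collectivity assemble more reliably
        m = g.sample_matrix(g.EnsembleSpec(S=60, mu=-0.2, sigma=0.4), seed=9)
        table = g.assembly_from_pairs_experiment(
            m, 6, 4000, seed=2, phi_bin_edges=np.array([0.0, 0.8, 1.2, np.inf])
        )
        by_bin = table.set_index("phi_bin")
        low = by_bin.iloc[0]
        high = by_bin.iloc[-1]
        assert low["n_trials"] > 100 and high["n_trials"] > 100
        assert low["success_rate"] > high["success_rate"]

    def test_set_size_validation(self):
        A = uniform_matrix(5, -0.1)
        m = g.InteractionMatrix(A=A, r=np.ones(5), K=np.ones(5))
        with pytest.raises(ConfigurationError):
            g.assembly_from_pairs_experiment(m, 6, 10)
        with pytest.raises(ConfigurationError):
            g.assembly_from_pairs_experiment(m, 2, 10)


class TestCoexistencePredicted:
    def test_matches_feasibility_and_stability(self):
        assert coexistence_predicted(uniform_matrix(4, -0.2))
        assert not coexistence_predicted(uniform_matrix(4, -1.5))
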