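import numpy as np
import pytest

from hiermut.architecture import make_architecture
from hiermut.dynamics import (clonal_integrate, clonal_matrix, clonal_steady_state,
                              flush_out_exponent, flush_out_rates,
                              generation_probabilities, integrate, per_tree_delta,
                              printed_rhs, rhs)
from hiermut.trees import DivisionTree, enumerate_trees, expected_differentiations

from conftest import random_architecture


def random_state(rng, arch):
    return rng.uniform(0, 1, arch.n + 1) * arch.N


class TestPerTreeDelta:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_closed_matches_brute_force(self, rng, n):
        # closed linear form vs the full double binomial sums, random states
        arch = random_architecture(rng, n)
        for tree in enumerate_trees(n):
            for _ in range(50 // len(enumerate_trees(n)) + 2):
                m = random_state(rng, arch)
                u = rng.uniform(0, 0.1)
                brute = per_tree_delta(tree, m, u, arch, method="brute")
                closed = per_tree_delta(tree, m, u, arch, method="closed")
                np.testing.assert_allclose(brute, closed, atol=1e-12)

    def test_single_level_closed_form(self):
        arch = make_architecture(1, (10, 20), 0.5)
        mu = np.array([0.3, 0.7])
        u = 0.01
        delta = per_tree_delta(DivisionTree((1,)), mu * arch.N, u, arch)
        np.testing.assert_allclose(delta, [
            2 * u * (1 - mu[0]),
            2 * (mu[0] + u * (1 - mu[0])) - 2 * mu[1],
        ])

    def test_clonal_form_at_u_zero(self, rng):
        # without mutation each tree moves mutants as 2 a_(k-1) (mu_(k-1) - mu_k)
        arch = random_architecture(rng, 3)
        mu = rng.uniform(0, 1, 4)
        for tree in enumerate_trees(3):
            delta = per_tree_delta(tree, mu * arch.N, 0.0, arch)
            a = (0,) + tree.a
            expected = [2 * a[k] * (mu[k - 1] - mu[k]) if k else 0.0 for k in range(4)]
            expected[3] = 2 * tree.a[2] * (mu[2] - mu[3])
            np.testing.assert_allclose(delta, expected, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_mutant_free_generation_telescopes(self, rng, n):
        # at mu = 0 each tree generates 2^(n+1) u mutants per update in total
        arch = random_architecture(rng, n)
        u = 1e-3
        for tree in enumerate_trees(n):
            delta = per_tree_delta(tree, np.zeros(n + 1), u, arch, method="brute")
            assert delta.sum() == pytest.approx(2 ** (n + 1) * u, rel=1e-10)

    def test_printed_beta_variant_differs(self, rng):
        arch = random_architecture(rng, 2)
        m = random_state(rng, arch)
        tree = enumerate_trees(2)[1]
        brute = per_tree_delta(tree, m, 1e-3, arch, method="brute")
        printed = per_tree_delta(tree, m, 1e-3, arch, method="printed_beta")
        assert not np.allclose(brute, printed)


class TestRHS:
    def test_derived_point_values(self, arch_n3_half):
        dm = rhs(np.zeros(4), arch_n3_half, 1e-3)
        np.testing.assert_allclose(dm, [3.125e-5, 1.46875e-3, 6.5e-3, 8e-3], rtol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_saturated_state_is_fixed_point(self, rng, n):
        arch = random_architecture(rng, n)
        np.testing.assert_allclose(rhs(arch.N, arch, 1e-3), 0, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_fixed_point_is_stable(self, rng, n):
        # linear system: Jacobian by finite differences, eigenvalues in left half plane
        arch = random_architecture(rng, n)
        u = 1e-3
        J = np.empty((n + 1, n + 1))
        base = rhs(arch.N.astype(float), arch, u)
        for j in range(n + 1):
            m = arch.N.astype(float)
            m[j] += 1e-6
            J[:, j] = (rhs(m, arch, u) - base) / 1e-6
        assert np.all(np.linalg.eigvals(J).real <= 1e-9)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_total_generation_rate(self, rng, n):
        arch = random_architecture(rng, n)
        u = rng.uniform(1e-4, 1e-2)
        assert rhs(np.zeros(n + 1), arch, u).sum() == pytest.approx(2 ** (n + 1) * u)

    @pytest.mark.parametrize("n", [2, 3])
    def test_generic_matches_printed_system(self, rng, n):
        for _ in range(100):
            v = rng.uniform()
            u = rng.uniform(0, 0.05)
            mu = rng.uniform(0, 1, n + 1)
            arch = make_architecture(n, (10,) * (n + 1), v)
            np.testing.assert_allclose(
                rhs(mu * arch.N, arch, u),
                printed_rhs(n, mu * arch.N, v, u, N=arch.N),
                atol=1e-12,
            )

    def test_printed_n1_factor_two(self, rng):
        mu = rng.uniform(0, 1, 2)
        u = 0.01
        arch = make_architecture(1, (10, 10), 0.5)
        corrected = printed_rhs(1, mu * arch.N, 0.5, u, N=arch.N)
        as_printed = printed_rhs(1, mu * arch.N, 0.5, u, N=arch.N, corrected=False)
        np.testing.assert_allclose(corrected, rhs(mu * arch.N, arch, u), atol=1e-12)
        assert as_printed[1] == pytest.approx(corrected[1] / 2)

    def test_printed_n3_degenerate_v1(self):
        dm = printed_rhs(3, np.zeros(4), 1.0, 1e-3)
        np.testing.assert_allclose(dm, [0.0, 0.0, 8e-3, 8e-3], atol=1e-15)

    def test_unsupported_printed_n(self):
        with pytest.raises(ValueError):
            printed_rhs(4, np.zeros(5), 0.5, 1e-3)


class TestIntegrate:
    def test_fixed_point_trajectory_constant(self, arch_n3_half):
        t = np.linspace(0, 500, 6)
        traj = integrate(arch_n3_half, 1e-3, arch_n3_half.N.astype(float), t)
        np.testing.assert_allclose(traj, np.tile(arch_n3_half.N, (6, 1)), rtol=1e-6)

    def test_no_mutation_no_mutants(self, arch_n3_half):
        traj = integrate(arch_n3_half, 0.0, np.zeros(4), np.linspace(0, 1000, 5))
        np.testing.assert_allclose(traj, 0, atol=1e-9)

    def test_approach_to_saturation(self):
        # every compartment fills to N_i once the stem level saturates
        arch = make_architecture(3, (100, 200, 400, 800), 0.1)
        traj = integrate(arch, 1e-3, np.zeros(4), np.linspace(0, 2e6, 11))
        assert np.all(traj[-1] / arch.N > 0.99)

    def test_selfrenewal_slows_stem_level(self):
        # monotone growth, more mature compartments lead, and the stem
        # compartment equilibrates far slower at v = 0.9 than at v = 0.1
        sizes = (100, 200, 400, 800)
        t = np.linspace(0, 200_000, 21)
        frac = {}
        for v in (0.9, 0.1):
            arch = make_architecture(3, sizes, v)
            traj = integrate(arch, 1e-3, np.zeros(4), t)
            assert np.all(np.diff(traj, axis=0) >= -1e-6)
            mu_end = traj[-1] / arch.N
            assert np.all(np.diff(mu_end) >= -1e-4)
            frac[v] = mu_end[0]
        assert frac[0.9] < 0.01 < frac[0.1]

    def test_rejects_out_of_bounds_start(self, arch_n3_half):
        with pytest.raises(ValueError):
            integrate(arch_n3_half, 1e-3, np.full(4, 1e6), [0, 10])


class TestGenerationProbabilities:
    def test_derived_vector(self, arch_n3_half):
        g = generation_probabilities(arch_n3_half)
        np.testing.assert_allclose(
            g, np.array([3.125e-5, 1.46875e-3, 6.5e-3, 8e-3]) / 0.016, rtol=1e-12)

    def test_shortest_tree_limit(self):
        g = generation_probabilities(make_architecture(3, (5,) * 4, 1.0))
        np.testing.assert_allclose(g, [0, 0, 0.5, 0.5], atol=1e-15)

    def test_independent_of_sizes_and_u(self):
        a = make_architecture(3, (65, 65, 65, 65), 0.7)
        b = make_architecture(3, (20, 40, 80, 120), 0.7)
        np.testing.assert_allclose(generation_probabilities(a, 1e-3),
                                   generation_probabilities(b, 1e-5), rtol=1e-9)

    def test_stem_share_decreasing_in_v(self):
        g0 = [generation_probabilities(make_architecture(3, (5,) * 4, v))[0]
              for v in np.linspace(0, 0.95, 8)]
        assert all(a >= b - 1e-15 for a, b in zip(g0, g0[1:]))


class TestFlushOut:
    @pytest.mark.parametrize("n,v,expected", [(3, 0.5, 2 * 0.5**6), (2, 0.5, 0.5)])
    def test_stem_rate_closed_form(self, n, v, expected):
        K = flush_out_rates(make_architecture(n, (5,) * (n + 1), v))
        assert K[0] == pytest.approx(expected, rel=1e-12)

    def test_binary_limit_rates(self):
        K = flush_out_rates(make_architecture(3, (5,) * 4, 0.0))
        np.testing.assert_allclose(K, [2, 4, 8])

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_rate_identity_against_clonal_rhs(self, rng, n):
        # independent route: K_k is the coefficient of mu_(k-1) in the u=0
        # brute-force tree-weighted system
        arch = random_architecture(rng, n)
        K = flush_out_rates(arch)
        for k in range(1, n + 1):
            m = np.zeros(n + 1)
            m[k - 1] = 0.37 * arch.sizes[k - 1]
            dm = rhs(m, arch, 0.0, method="brute")
            assert dm[k] == pytest.approx(K[k - 1] * 0.37, rel=1e-9)
        np.testing.assert_allclose(K, 2 * expected_differentiations(arch), rtol=1e-12)

    def test_rates_non_increasing_in_each_v(self):
        base = [1.0, 0.4, 0.6, 0.5, 0.0]
        for j in (1, 2, 3):
            prev = None
            for vj in np.linspace(0, 1, 6):
                v = list(base)
                v[j] = vj
                K = flush_out_rates(make_architecture(4, (5,) * 5, v))
                if prev is not None:
                    assert np.all(K <= prev + 1e-12)
                prev = K

    @pytest.mark.parametrize("n,i,gamma", [(3, 1, 6), (3, 2, 2), (3, 3, 0), (4, 2, 6)])
    def test_exponent_recovery(self, n, i, gamma):
        assert flush_out_exponent(n, i) == pytest.approx(gamma, abs=0.05)

    def test_exponent_index_validation(self):
        with pytest.raises(ValueError):
            flush_out_exponent(3, 4)


class TestClonalDynamics:
    def test_steady_state_proportional_to_sizes(self):
        arch = make_architecture(3, (20, 40, 80, 120), 0.5)
        t = np.linspace(0, 40_000, 11)
        traj = clonal_integrate(arch, [4, 0, 0, 0], t)
        np.testing.assert_allclose(traj[:, 0], 4.0, rtol=1e-8)
        np.testing.assert_allclose(traj[-1], [4, 8, 16, 24], rtol=1e-5)
        np.testing.assert_allclose(clonal_steady_state(arch, 4.0), [4, 8, 16, 24])

    def test_flush_out_without_stem_seed(self):
        arch = make_architecture(3, (20, 40, 80, 120), 0.5)
        traj = clonal_integrate(arch, [0, 10, 5, 0], np.linspace(0, 40_000, 5))
        np.testing.assert_allclose(traj[-1], 0, atol=1e-4)

    def test_matrix_is_lower_bidiagonal_with_zero_stem_row(self, rng):
        arch = random_architecture(rng, 3)
        A = clonal_matrix(arch)
        assert np.all(A[0] == 0)
        for k in range(1, 4):
            assert A[k, k] < 0 or arch.selfrenewal[1] == 1.0
        assert np.all(np.triu(A, 1) == 0)
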