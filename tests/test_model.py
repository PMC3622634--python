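import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

import admixhmm as ax
from admixhmm.model import (ResidualStick, betabinom_log_factor,
                            block_emission_logprob, individual_emission_logprob,
                            table_lookup)


class TestStickWeights:
    def test_halving_sticks(self):
        sw = ax.stick_weights([0.5, 0.5, 0.5])
        np.testing.assert_allclose(sw.v, [0.5, 0.25, 0.125])
        assert sw.super_mass == pytest.approx(0.125)

    def test_first_stick_one(self):
        sw = ax.stick_weights([1.0, 0.7])
        np.testing.assert_allclose(sw.v, [1.0, 0.0])
        assert sw.super_mass == 0.0

    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_telescoping_identity(self, V):
        sw = ax.stick_weights(V)
        assert sw.v.sum() + sw.super_mass == pytest.approx(1.0, abs=1e-12)
        assert np.all(sw.v >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ax.stick_weights([0.5, 1.5])


class TestStickPosterior:
    def test_prior_dominated_mean(self):
        rng = np.random.default_rng(1)
        draws = [ax.update_stick_posterior(np.zeros(3), rng).V[0]
                 for _ in range(4000)]
        # c = 0 everywhere: V_q ~ Beta(1, 2), mean 1/3
        assert np.mean(draws) == pytest.approx(1 / 3, abs=0.02)

    def test_concentrated_mean(self):
        rng = np.random.default_rng(2)
        draws = [ax.update_stick_posterior([100.0, 0.0], rng).V[0]
                 for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(101 / 103, abs=0.005)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            c = rng.integers(0, 50, size=rng.integers(1, 8)).astype(float)
            sw = ax.update_stick_posterior(c, rng)
            assert sw.v.sum() + sw.super_mass == pytest.approx(1.0, abs=1e-12)


class TestResidualStick:
    def test_first_assignment_gets_first_label(self):
        rng = np.random.default_rng(4)
        rs = ResidualStick(0, rng)
        assert rs.sample() >= 0

    def test_size_biased_ordering(self):
        """New labels follow the residual stick's size-biased distribution:
        P(first index) = E[V] = 1/2 for Beta(1,1) sticks."""
        rng = np.random.default_rng(5)
        counts = np.zeros(30)
        n = 4000
        for _ in range(n):
            rs = ResidualStick(3, rng)
            counts[rs.sample() - 3] += 1
        p = counts / n
        for m, expected in enumerate([0.5, 0.25, 0.125]):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(p[m] - expected) < 4 * se
        assert np.all(np.diff(counts[:5]) <= 0)


class TestSegmentWeights:
    def test_single_snp_segment(self):
        w = ax.segment_weight(3, 3, np.full(10, 0.2))
        np.testing.assert_allclose(w, [1.0])

    def test_no_recombination_gives_geometric_mean(self):
        w = ax.segment_weight(0, 3, np.zeros(10))
        np.testing.assert_allclose(w, 0.25)

    def test_expected_event_numerator(self):
        r = np.zeros(5)
        r[1], r[2] = 0.1, 0.3
        w = ax.segment_weight(0, 2, r)
        np.testing.assert_allclose(w, 1.4 / 3)

    def test_first_snp_scheme(self):
        r = np.array([0.0, 0.1, 0.3])
        w = ax.segment_weight(0, 2, r, scheme="first_snp")
        np.testing.assert_allclose(w, [1.0, 0.1, 0.3])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ax.segment_weight(3, 2, np.zeros(5))


class TestEmissionTable:
    def test_empty_population_is_uniform(self):
        # y = 0, n = 0, K_j = 2 -> (0+1)/(0+2) = 1/2
        S = np.array([[0, 0], [1, 1]])
        Q = np.zeros_like(S)
        sid, K = ax.compact_states(S)
        probs = ax.update_emission_table(sid, Q, n_pops=2, K=K)
        np.testing.assert_allclose(probs[1], 0.5)

    def test_add_one_smoothing(self):
        # 9 chains in population 0 at one SNP; state 0 seen 3 times, K_j = 3
        S = np.array([[0], [0], [0], [1], [1], [1], [2], [2], [2]])
        Q = np.zeros_like(S)
        sid, K = ax.compact_states(S)
        probs = ax.update_emission_table(sid, Q, n_pops=1, K=K)
        np.testing.assert_allclose(probs[0, :, 0], 1 / 3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        S = rng.integers(0, 4, size=(10, 6))
        Q = rng.integers(0, 3, size=(10, 6))
        sid, K = ax.compact_states(S)
        probs = ax.update_emission_table(sid, Q, n_pops=3, K=K)
        sums = probs.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert np.all(probs[:, 0, :] > 0)


class TestTransitionRow:
    def test_gamma_zero_identity(self):
        sw = ax.stick_weights([0.6, 0.5])
        row = ax.transition_row(0.0, sw, 1)
        expected = np.zeros(3)
        expected[1] = 1.0
        np.testing.assert_allclose(row, expected)

    def test_gamma_one_is_stationary(self):
        sw = ax.stick_weights([0.6, 0.5])
        row = ax.transition_row(1.0, sw, 0)
        np.testing.assert_allclose(row, sw.full())

    def test_row_sums_to_one(self):
        sw = ax.stick_weights([0.3, 0.9, 0.1])
        for g in (0.0, 0.2, 0.77, 1.0):
            assert ax.transition_row(g, sw, 2).sum() == pytest.approx(1.0, abs=1e-12)


class TestChainPrior:
    def test_single_snp_factor_value(self):
        # 2N=2, xi=0, alpha*r=0.1: Gamma(0.1)Gamma(2.9)/(Gamma(3)Gamma(0.1)Gamma(0.9))
        got = np.exp(betabinom_log_factor([0], 2, [0.1]))[0]
        expected = np.exp(gammaln(2.9) - gammaln(3.0) - gammaln(0.9))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.855, abs=5e-4)

    def test_factor_matches_quadrature(self):
        """The marginalized factor equals the Beta integral
        int gamma^xi (1-gamma)^(2N-xi) Beta(gamma; ar, 1-ar) d gamma."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            two_n = int(rng.integers(2, 12))
            xi = int(rng.integers(0, two_n + 1))
            ar = float(rng.uniform(0.01, 0.9))
            got = np.exp(betabinom_log_factor([xi], two_n, [ar]))[0]
            # integrand gamma^(xi+ar-1) (1-gamma)^(2N-xi-ar) / B(ar, 1-ar):
            # endpoint singularities handled by quad's algebraic weighting
            val, _ = quad(lambda g: 1.0, 0, 1, weight="alg",
                          wvar=(xi + ar - 1, two_n - xi - ar))
            val *= np.exp(-gammaln(ar) - gammaln(1 - ar))
            assert got == pytest.approx(val, rel=1e-8)

    def test_beta_binomial_normalization(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            two_n = int(rng.integers(2, 20))
            ar = float(rng.uniform(0.01, 0.95))
            xs = np.arange(two_n + 1)
            probs = np.exp(gammaln(two_n + 1) - gammaln(xs + 1)
                           - gammaln(two_n - xs + 1)
                           + betabinom_log_factor(xs, two_n, ar))
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_no_event_chains(self):
        # all chains constant, v_0 = 1: stick terms contribute log(1) = 0
        Q = np.zeros((4, 3), dtype=int)
        I = np.zeros((4, 3), dtype=bool)
        sw = ax.stick_weights([1.0])
        r = np.array([0.0, 0.05, 0.05])
        lp = ax.chain_prior_logprob(Q, I, sw, alpha=0.2, r=r)
        expected = betabinom_log_factor([0, 0], 4, 0.2 * r[1:]).sum()
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_exchangeable_in_individuals(self):
        rng = np.random.default_rng(11)
        sw = ax.stick_weights([0.5, 0.6, 0.7])
        r = np.concatenate([[0.0], rng.uniform(0.01, 0.3, 4)])
        Q = rng.integers(0, 3, size=(6, 5))
        I = np.zeros((6, 5), dtype=bool)
        I[:, 1:] = True  # every SNP may be an event: Q free
        lp1 = ax.chain_prior_logprob(Q, I, sw, 0.2, r)
        perm = rng.permutation(3)
        Qp = np.vstack([Q[2 * i:2 * i + 2] for i in perm])
        lp2 = ax.chain_prior_logprob(Qp, I, sw, 0.2, r)
        assert lp1 == pytest.approx(lp2, rel=1e-12)

    def test_inconsistent_qi_rejected(self):
        Q = np.array([[0, 1]])
        I = np.zeros((1, 2), dtype=bool)
        with pytest.raises(ValueError):
            ax.chain_prior_logprob(Q, I, ax.stick_weights([0.5]), 0.2,
                                   np.array([0.0, 0.1]))


def _toy_emission_setup(seed=12, L=6, n_pops=2):
    """Small aligned (states, table, weights) setup for emission tests."""
    rng = np.random.default_rng(seed)
    S = rng.integers(0, 3, size=(4, L))
    Q = rng.integers(0, n_pops, size=(4, L))
    sid, K = ax.compact_states(S)
    probs = ax.update_emission_table(sid, Q, n_pops, K)
    W = rng.uniform(0.1, 1.0, size=(4, L))
    return sid, Q, probs, W, K


class TestBlockEmission:
    def test_uniform_table_is_symmetric(self):
        L = 4
        sid = np.zeros((2, L), dtype=int)
        K = np.full(L, 2)
        probs = np.full((2, 2, L), 0.5)
        W = np.full((2, L), 1.0)
        vals = {(q1, q2, d): block_emission_logprob(
            (0, L - 1), sid, np.array([[q1] * L, [q2] * L]), W, probs, d, K)
            for q1 in (0, 1) for q2 in (0, 1) for d in (0, 1)}
        assert len(set(round(v, 12) for v in vals.values())) == 1

    def test_single_snp_block(self):
        sid = np.zeros((2, 1), dtype=int)
        probs = np.full((1, 1, 1), 0.8)
        W = np.ones((2, 1))
        val = block_emission_logprob((0, 0), sid, np.zeros((2, 1), dtype=int),
                                     W, probs, 0, np.array([1]))
        assert val == pytest.approx(2 * np.log(0.8))

    def test_matches_scalar_evaluation(self):
        """Weighted product over a 2-segment block equals a direct scalar
        re-evaluation of the emission formula."""
        sid, Q, probs, W, K = _toy_emission_setup()
        a, b = 1, 4
        for delta in (0, 1):
            got = block_emission_logprob((a, b), sid[:2], Q[:2], W[:2],
                                         probs, delta, K)
            expected = 0.0
            for l in (0, 1):
                src = l if delta == 0 else 1 - l
                for j in range(a, b + 1):
                    expected += W[src, j] * np.log(
                        probs[Q[l, j], sid[src, j], j])
            assert got == pytest.approx(expected, rel=1e-12)

    def test_absent_state_rejected(self):
        sid = np.array([[1], [0]])
        probs = np.zeros((1, 2, 1))
        probs[0, 0, 0] = 1.0  # state 1 absent from the table
        with pytest.raises(ValueError):
            block_emission_logprob((0, 0), sid, np.zeros((2, 1), dtype=int),
                                   np.ones((2, 1)), probs, 0, np.array([2]))


class TestIndividualEmission:
    def test_matches_delta_enumeration(self):
        """The switch-error forward recursion equals brute-force summation
        over all 2^B switch configurations."""
        sid, Q, probs, W, K = _toy_emission_setup(seed=13, L=9)
        dr_sites = [3, 6]
        for eps in (0.5, 0.25):
            got = individual_emission_logprob(sid[:2], Q[:2], W[:2], probs,
                                              dr_sites, 9, eps, K)
            blocks = [(0, 2), (3, 5), (6, 8)]
            total = 0.0
            for deltas in itertools.product([0, 1], repeat=3):
                w = 1.0
                prev = 0
                for d in deltas:
                    w *= eps if d != prev else (1 - eps)
                    prev = d
                pe = 1.0
                for b, d in zip(blocks, deltas):
                    pe *= np.exp(block_emission_logprob(b, sid[:2], Q[:2],
                                                        W[:2], probs, d, K))
                total += w * pe
            assert got == pytest.approx(np.log(total), rel=1e-10)

    def test_single_block_mixes_anchor(self):
        sid, Q, probs, W, K = _toy_emission_setup(seed=14, L=4)
        eps = 0.3
        got = individual_emission_logprob(sid[:2], Q[:2], W[:2], probs,
                                          [], 4, eps, K)
        e0 = block_emission_logprob((0, 3), sid[:2], Q[:2], W[:2], probs, 0, K)
        e1 = block_emission_logprob((0, 3), sid[:2], Q[:2], W[:2], probs, 1, K)
        expected = np.log((1 - eps) * np.exp(e0) + eps * np.exp(e1))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_strand_swap_invariance_at_half(self):
        """With eps = 0.5 the likelihood is invariant to swapping the two
        strands of the individual."""
        rng = np.random.default_rng(15)
        for _ in range(5):
            sid, Q, probs, W, K = _toy_emission_setup(seed=rng.integers(1e6),
                                                      L=8)
            dr = [2, 5]
            a = individual_emission_logprob(sid[:2], Q[:2], W[:2], probs,
                                            dr, 8, 0.5, K)
            swap = np.array([1, 0])
            b = individual_emission_logprob(sid[swap], Q[swap], W[swap], probs,
                                            dr, 8, 0.5, K)
            assert a == pytest.approx(b, rel=1e-10)


def test_table_lookup_super_state_is_uniform():
    probs = np.full((1, 3, 2), 1 / 3)
    K = np.array([3, 3])
    assert table_lookup(probs, 5, 0, 1, K) == pytest.approx(1 / 3)
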