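"""Exact equivalence of the production forward/backward kernels with
brute-force enumeration over all (Q, I, delta) configurations on small
instances, plus the validity of the collapsed per-individual Gibbs update
against the enumerated joint posterior."""

import numpy as np
import pytest

import admixhmm as ax
from admixhmm.fit import IndividualModel, backward_pass, forward_summation
from admixhmm.model import betabinom_log_factor

from _oracle import enumerate_individual, random_toy


def _make_im(toy):
    return IndividualModel(
        ev_pos=np.arange(toy["E"].shape[0]), r1=toy["r1"], r2=toy["r2"],
        fl=toy["fl"], E=toy["E"], g1=toy["g1"], g2a=toy["g2a"],
        g2b=toy["g2b"], v=toy["v"], eps=toy["eps"])


@pytest.fixture(scope="module")
def toys():
    rng = np.random.default_rng(421)
    return [random_toy(rng) for _ in range(50)]


class TestOracleEquivalence:
    def test_forward_marginals_match_enumeration(self, toys):
        """Filtering marginals over (q1, q2, delta) at every event equal
        exhaustive enumeration, relative error < 1e-9."""
        for toy in toys:
            im = _make_im(toy)
            M, _ = forward_summation(im)
            oracle = enumerate_individual(**toy)
            for t in range(im.n_events):
                dense = np.zeros_like(M[t])
                for (a, b, d), p in oracle.filtering[t].items():
                    dense[a, b, d] = p
                np.testing.assert_allclose(M[t], dense, rtol=1e-9, atol=1e-12)

    def test_loglik_matches_enumeration(self, toys):
        for toy in toys:
            im = _make_im(toy)
            _, loglik = forward_summation(im)
            oracle = enumerate_individual(**toy)
            assert loglik == pytest.approx(oracle.log_z, rel=1e-9)

    def test_map_path_matches_enumeration(self, toys):
        """The maximization backward pass recovers the exact joint MAP
        configuration (including events and switch states)."""
        for toy in toys:
            im = _make_im(toy)
            M, _ = forward_summation(im)
            q1, q2, d, i1, i2 = backward_pass(im, M, mode="maximize")
            got = list(zip(q1.tolist(), q2.tolist(), d.tolist(),
                           i1.tolist(), i2.tolist()))
            oracle = enumerate_individual(**toy)
            # compare path probabilities (ties may pick different argmaxes)
            got_lp = _path_logprob(toy, got)
            assert got_lp == pytest.approx(oracle.map_logprob, rel=1e-9)

    def test_backward_sampling_frequencies(self):
        """Sampled paths follow the enumerated posterior (multinomial 3 SE)."""
        rng = np.random.default_rng(77)
        toy = random_toy(rng, max_events=3, max_pops=3)
        im = _make_im(toy)
        M, _ = forward_summation(im)
        oracle = enumerate_individual(**toy)
        n = 20_000
        counts = {}
        for _ in range(n):
            q1, q2, d, i1, i2 = backward_pass(im, M, rng, mode="sample")
            key = tuple(zip(q1.tolist(), q2.tolist(), d.tolist(),
                            i1.tolist(), i2.tolist()))
            counts[key] = counts.get(key, 0) + 1
        for path, p in oracle.posterior.items():
            if p < 5e-4:
                continue
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(path, 0) / n - p) < max(3.5 * se, 2e-3), path


def _path_logprob(toy, path):
    """Directly price one (Q, I, delta) configuration (independent check)."""
    E, v, eps = toy["E"], toy["v"], toy["eps"]
    lp = 0.0
    for t, (q1, q2, d, i1, i2) in enumerate(path):
        if t == 0:
            lp += np.log(v[q1] * v[q2] * ((1 - eps) if d == 0 else eps))
        else:
            pq1, pq2, pd = path[t - 1][0], path[t - 1][1], path[t - 1][2]
            g1 = toy["g1"][t] if toy["r1"][t] else 0.0
            lp += np.log(g1 if i1 else 1 - g1)
            g2 = (toy["g2b"][t] if i1 else toy["g2a"][t]) if toy["r2"][t] else 0.0
            lp += np.log(g2 if i2 else 1 - g2)
            lp += np.log(v[q1]) if i1 else (0.0 if q1 == pq1 else -np.inf)
            lp += np.log(v[q2]) if i2 else (0.0 if q2 == pq2 else -np.inf)
            if toy["fl"][t]:
                lp += np.log((1 - eps) if d == pd else eps)
            elif d != pd:
                lp = -np.inf
        lp += E[t, 0, q1] + E[t, 1, q2] if d == 0 else E[t, 1, q1] + E[t, 0, q2]
    return lp


class TestDegenerateChains:
    def test_flat_emissions_posterior_is_prior(self):
        """Uniform emissions: the marginal at the last event is the prior
        propagated through the chain, which for gamma-predictive 0 equals
        the initial stick distribution."""
        P, T = 3, 3
        v = np.array([0.5, 0.3, 0.2])
        im = IndividualModel(
            ev_pos=np.arange(T), r1=np.array([False, True, True]),
            r2=np.array([False, True, True]), fl=np.zeros(T, dtype=bool),
            E=np.zeros((T, 2, P)), g1=np.zeros(T), g2a=np.zeros(T),
            g2b=np.zeros(T), v=v, eps=0.5)
        M, _ = forward_summation(im)
        marg1 = M[T - 1].sum(axis=(1, 2))
        np.testing.assert_allclose(marg1, v, atol=1e-12)

    def test_gamma_zero_freezes_chain(self):
        """With zero admixture predictive the chain keeps its first state."""
        rng = np.random.default_rng(3)
        P, T = 2, 4
        im = IndividualModel(
            ev_pos=np.arange(T), r1=np.ones(T, dtype=bool),
            r2=np.ones(T, dtype=bool), fl=np.zeros(T, dtype=bool),
            E=np.log(rng.uniform(0.2, 1, size=(T, 2, P))),
            g1=np.zeros(T), g2a=np.zeros(T), g2b=np.zeros(T),
            v=np.array([0.6, 0.4]), eps=0.5)
        M, _ = forward_summation(im)
        q1, q2, d, i1, i2 = backward_pass(im, M, rng, mode="sample")
        assert np.all(q1 == q1[0]) and np.all(q2 == q2[0])
        assert i1.sum() == 0 and i2.sum() == 0

    def test_no_events_means_constant_chain(self):
        rng = np.random.default_rng(4)
        P, T = 3, 4
        im = IndividualModel(
            ev_pos=np.arange(T), r1=np.zeros(T, dtype=bool),
            r2=np.zeros(T, dtype=bool), fl=np.zeros(T, dtype=bool),
            E=np.log(rng.uniform(0.2, 1, size=(T, 2, P))),
            g1=np.full(T, 0.5), g2a=np.full(T, 0.5), g2b=np.full(T, 0.5),
            v=np.full(3, 1 / 3), eps=0.5)
        M, _ = forward_summation(im)
        for mode in ("sample", "maximize"):
            q1, q2, d, i1, i2 = backward_pass(im, M, rng, mode=mode)
            assert np.unique(q1).size == 1 and np.unique(q2).size == 1


class TestCollapsedGibbsValidity:
    def test_gibbs_occupancy_matches_joint_posterior(self):
        """Alternating per-individual updates leave the joint
        Pr(X | Q, delta) Pr(Q, I | v) invariant: long-run occupancy
        frequencies match the enumerated two-individual posterior (3 SE).

        Two individuals, two events each, fixed emission table and sticks;
        the event predictives for one individual are recomputed from the
        other's current events, exactly as in the fitting loop.
        """
        rng = np.random.default_rng(2024)
        P, T = 2, 2
        alpha_r = 0.08
        v = np.array([0.55, 0.45])
        eps = 0.5
        E = [np.log(rng.uniform(0.1, 1.0, size=(T, 2, P))) for _ in range(2)]
        r1 = np.array([False, True])
        fl = np.array([False, True])
        two_n = 4

        def g_for(xi_other):
            # sequential pair predictive given the other individual's events
            g1 = (xi_other + alpha_r) / (two_n - 1)
            g2a = (xi_other + alpha_r) / two_n
            g2b = (xi_other + 1 + alpha_r) / two_n
            return g1, g2a, g2b

        # enumerate the exact joint over both individuals: per individual
        # the path is ((q1,q2,d),(q1',q2',d',i1,i2)); joint prior couples
        # through the per-SNP Beta-binomial factor over xi = sum of events
        def path_weight_emission(i, path):
            w = 0.0
            for t, st in enumerate(path):
                a, b, d = st[0], st[1], st[2]
                w += E[i][t, 0, a] + E[i][t, 1, b] if d == 0 else \
                    E[i][t, 1, a] + E[i][t, 0, b]
            return w

        def enumerate_paths():
            paths = []
            for a0 in range(P):
                for b0 in range(P):
                    for d0 in (0, 1):
                        for i1 in (0, 1):
                            for i2 in (0, 1):
                                for a1 in (range(P) if i1 else (a0,)):
                                    for b1 in (range(P) if i2 else (b0,)):
                                        for d1 in (0, 1):
                                            paths.append(((a0, b0, d0),
                                                          (a1, b1, d1, i1, i2)))
            return paths

        paths = enumerate_paths()
        joint = {}
        for p0 in paths:
            for p1 in paths:
                lp = 0.0
                for i, p in enumerate((p0, p1)):
                    (a0, b0, d0), (a1, b1, d1, i1, i2) = p
                    lp += np.log(v[a0] * v[b0]) + np.log(0.5)  # delta anchor
                    if i1:
                        lp += np.log(v[a1])
                    if i2:
                        lp += np.log(v[b1])
                    lp += np.log(0.5)  # delta flip factor, eps = 0.5
                    lp += path_weight_emission(i, p)
                xi = p0[1][3] + p0[1][4] + p1[1][3] + p1[1][4]
                lp += betabinom_log_factor([xi], two_n, [alpha_r])[0]
                joint[(p0, p1)] = lp
        mx = max(joint.values())
        z = sum(np.exp(lp - mx) for lp in joint.values())
        post = {k: np.exp(lp - mx) / z for k, lp in joint.items()}
        # marginal of individual 0's final (q1, q2)
        marg = np.zeros((P, P))
        for (p0, _), pr in post.items():
            marg[p0[1][0], p0[1][1]] += pr

        # run the alternating collapsed Gibbs with the production kernels
        state = [((0, 0, 0), (0, 0, 0, 0, 0)), ((0, 0, 0), (0, 0, 0, 0, 0))]
        occ = np.zeros((P, P))
        n_sweeps = 6000
        for sweep in range(n_sweeps):
            for i in (0, 1):
                other = state[1 - i][1]
                xi_other = other[3] + other[4]
                g1, g2a, g2b = g_for(xi_other)
                im = IndividualModel(
                    ev_pos=np.arange(T), r1=r1, r2=r1, fl=fl, E=E[i],
                    g1=np.array([0.0, g1]), g2a=np.array([0.0, g2a]),
                    g2b=np.array([0.0, g2b]), v=v, eps=eps)
                M, _ = forward_summation(im)
                q1, q2, d, e1, e2 = backward_pass(im, M, rng, mode="sample")
                state[i] = ((q1[0], q2[0], d[0]),
                            (q1[1], q2[1], d[1], e1[1], e2[1]))
            f = state[0][1]
            occ[f[0], f[1]] += 1
        occ /= n_sweeps
        for a in range(P):
            for b in range(P):
                se = np.sqrt(marg[a, b] * (1 - marg[a, b]) / n_sweeps)
                # autocorrelation inflates the effective SE; allow 5x
                assert abs(occ[a, b] - marg[a, b]) < max(5 * 3 * se, 0.01), \
                    (a, b, occ[a, b], marg[a, b])
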