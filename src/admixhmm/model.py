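"""Probability model for the population-admixture layer.

The admixture layer is an infinite-state hidden Markov model over
population-origin chains. Its pieces, all in log space:

* a stick-breaking prior over population weights v_q = V_q * prod_{t<q}(1-V_t),
  with every unoccupied label collapsed into a single "super" state carrying
  the residual mass 1 - sum_{q<=q*} v_q;
* segment emissions Pr(s | q) -- how often haplotype state s occurs in
  population q at a SNP -- raised to per-SNP weights w that discount the
  redundancy of SNPs within a haplotype segment, and summed over possible
  phasing switch errors delta at double-recombination sites (switch-error
  probability epsilon, default 0.5);
* a heterogeneous Markov chain over population origins whose per-SNP
  admixture rate gamma_j carries a Dirichlet(alpha*r_j, 1-alpha*r_j) prior
  (alpha default 0.2, r_j the haplotype recombination probability from the
  segmentation layer) and is integrated out, leaving a Beta-binomial factor
  per SNP over the total event count xi_j across all 2N chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

DEFAULT_ALPHA = 0.2
DEFAULT_EPSILON = 0.5


# ---------------------------------------------------------------------------
# stick-breaking machinery (shared by both model layers)
# ---------------------------------------------------------------------------

@dataclass
class StickWeights:
    """Truncated stick-breaking weights plus the residual super-state mass."""

    V: np.ndarray          # Beta stick fractions, length q*
    v: np.ndarray          # realized weights, length q*
    super_mass: float      # 1 - sum(v): mass of all unoccupied labels

    @property
    def n_occupied(self) -> int:
        return self.v.size

    def full(self) -> np.ndarray:
        """Weights with the super-state mass appended as the last entry."""
        return np.append(self.v, self.super_mass)


def stick_weights(V) -> StickWeights:
    """Realize v_q = V_q * prod_{t<q}(1 - V_t) from Beta fractions V."""
    V = np.asarray(V, dtype=float)
    if np.any((V < 0) | (V > 1)):
        raise ValueError("stick fractions must lie in [0, 1]")
    rem = np.concatenate([[1.0], np.cumprod(1.0 - V)])
    v = V * rem[:-1]
    return StickWeights(V=V, v=v, super_mass=float(rem[-1]))


def update_stick_posterior(c, rng: np.random.Generator) -> StickWeights:
    """Sample stick weights from their posterior given occupancy counts.

    ``c_q`` counts occurrences of population q at admixture events or chain
    starts; the conjugate posterior is V_q ~ Beta(c_q + 1, sum_{t>q} c_t + 2).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    tail = np.concatenate([np.cumsum(c[::-1])[::-1][1:], [0.0]])
    V = rng.beta(c + 1.0, tail + 2.0)
    return stick_weights(V)


class ResidualStick:
    """Lazily realized sticks inside the super-state mass.

    When a backward pass selects the super state, the concrete label of the
    new population is drawn from the residual stick-breaking measure:
    sequential Beta(1,1) sticks within the super mass, so the first unused
    index is the most probable (size-biased ordering). Labels are shared
    within one sweep: two super selections may land on the same new label.
    """

    def __init__(self, q_star: int, rng: np.random.Generator):
        self.base = q_star
        self._rng = rng
        self._V: list[float] = []
        self.max_issued = q_star - 1

    def sample(self) -> int:
        m = 0
        while True:
            if m == len(self._V):
                self._V.append(float(self._rng.beta(1.0, 1.0)))
            if self._rng.random() < self._V[m]:
                label = self.base + m
                self.max_issued = max(self.max_issued, label)
                return label
            m += 1


def sample_new_label(residual: ResidualStick) -> int:
    """Draw a fresh population label from the residual stick."""
    return residual.sample()


# ---------------------------------------------------------------------------
# emission table
# ---------------------------------------------------------------------------

def compact_states(S) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP dense re-indexing of haplotype states.

    Returns ``sid`` of the same shape with states renumbered 0..K_j-1 within
    each SNP column, and the per-SNP distinct-state count ``K_j``.
    """
    S = np.asarray(S)
    n_chains, L = S.shape
    sid = np.empty_like(S, dtype=np.int64)
    K = np.empty(L, dtype=np.int64)
    for j in range(L):
        uniq, inv = np.unique(S[:, j], return_inverse=True)
        sid[:, j] = inv
        K[j] = uniq.size
    return sid, K


def update_emission_table(sid, Q, n_pops: int, K) -> np.ndarray:
    """Add-one-smoothed haplotype-state frequencies per population per SNP.

    Entry [q, s, j] = (y + 1) / (n + K_j) where y counts chains with state s
    and population q at SNP j, and n is the number of chains in population q
    at SNP j. A population absent at a SNP (n = 0) therefore gets the
    uniform row 1/K_j. States s >= K_j are zero-padded.
    """
    sid = np.asarray(sid)
    Q = np.asarray(Q)
    if sid.shape != Q.shape:
        raise ValueError("state and population matrices must align")
    K = np.asarray(K)
    n_chains, L = sid.shape
    s_max = int(K.max())
    Y = np.zeros((n_pops, s_max, L))
    cols = np.broadcast_to(np.arange(L), sid.shape)
    np.add.at(Y, (Q, sid, cols), 1.0)
    n = Y.sum(axis=1, keepdims=True)
    probs = (Y + 1.0) / (n + K[None, None, :])
    valid = np.arange(s_max)[None, :, None] < K[None, None, :]
    return np.where(valid, probs, 0.0)


def table_lookup(probs: np.ndarray, q: int, s: int, j: int, K) -> float:
    """Pr(s | q) at SNP j; labels beyond the table are unoccupied (uniform)."""
    if q >= probs.shape[0]:
        return 1.0 / float(np.asarray(K)[j])
    return float(probs[q, s, j])


# ---------------------------------------------------------------------------
# segment weights
# ---------------------------------------------------------------------------

def segment_weight(a: int, b: int, r, scheme: str = "segment_mean") -> np.ndarray:
    """Per-SNP emission weights for the segment [a, b] (inclusive, 0-based).

    Default scheme: the constant (1 + sum_{j'=a+1}^{b} r_{j'}) / (b - a + 1),
    whose numerator is the expected number of recombination events within
    the segment -- the weighted product of per-SNP emissions then equals the
    geometric mean of the segment raised to that expected count. The
    alternative "first_snp" scheme puts weight 1 on the first SNP of the
    segment and r_j elsewhere.
    """
    if b < a:
        raise ValueError("segment end before start")
    r = np.asarray(r, dtype=float)
    if scheme == "segment_mean":
        w = (1.0 + r[a + 1 : b + 1].sum()) / (b - a + 1)
        return np.full(b - a + 1, w)
    if scheme == "first_snp":
        w = r[a : b + 1].copy()
        w[0] = 1.0
        return w
    raise ValueError(f"unknown weight scheme {scheme!r}")


def build_chain_weights(seg_starts: list[np.ndarray], L: int, r,
                        scheme: str = "segment_mean") -> np.ndarray:
    """Weights w for every chain and SNP given per-chain segment starts."""
    n_chains = len(seg_starts)
    W = np.empty((n_chains, L))
    for c, starts in enumerate(seg_starts):
        bounds = np.append(starts, L)
        for k in range(starts.size):
            a, b = int(bounds[k]), int(bounds[k + 1]) - 1
            W[c, a : b + 1] = segment_weight(a, b, r, scheme)
    return W


# ---------------------------------------------------------------------------
# emission log-probabilities
# ---------------------------------------------------------------------------

def block_emission_logprob(span, sid_pair, q_pair, weights_pair, probs, delta,
                           K=None) -> float:
    """Log emission of one double-recombination block for a fixed delta.

    ``span`` = (a, b) inclusive SNP bounds of the block; ``sid_pair``,
    ``q_pair`` and ``weights_pair`` are (2, L) arrays of haplotype states,
    population origins and segment weights for the two strands. With
    delta = 1 the strands' states and weights are swapped: population q on
    strand l emits the state observed on strand 1-l, with that strand's
    weight.
    """
    a, b = span
    total = 0.0
    for l in range(2):
        src = l if delta == 0 else 1 - l
        for j in range(a, b + 1):
            p = table_lookup(probs, int(q_pair[l, j]), int(sid_pair[src, j]), j, K)
            if p <= 0.0:
                raise ValueError("haplotype state absent from emission table")
            total += weights_pair[src, j] * np.log(p)
    return total


def individual_emission_logprob(sid_pair, q_pair, weights_pair, probs,
                                dr_sites, L: int,
                                epsilon: float = DEFAULT_EPSILON,
                                K=None) -> float:
    """Log Pr(X_i | Q_i): emission summed over phasing switch errors.

    ``dr_sites`` are the interior double-recombination SNP indices (strictly
    between 0 and L-1) at which the switch state delta may flip. The sum
    over all delta vectors runs as a two-state forward recursion along the
    blocks; the chain is anchored at delta = 0 before the first block, so
    the first block flips with probability epsilon. With the default
    epsilon = 0.5 the anchor choice is immaterial.
    """
    sites = [s for s in dr_sites if 0 < s < L]
    starts = [0] + sites
    ends = sites + [L]
    # forward over delta in log space
    f = None
    for blk, (a, b) in enumerate(zip(starts, ends)):
        e0 = block_emission_logprob((a, b - 1), sid_pair, q_pair, weights_pair,
                                    probs, 0, K)
        e1 = block_emission_logprob((a, b - 1), sid_pair, q_pair, weights_pair,
                                    probs, 1, K)
        if blk == 0:
            f = np.array([np.log(1 - epsilon) + e0, np.log(epsilon) + e1])
        else:
            stay, flip = np.log(1 - epsilon), np.log(epsilon)
            f = np.array([
                logsumexp([f[0] + stay, f[1] + flip]) + e0,
                logsumexp([f[0] + flip, f[1] + stay]) + e1,
            ])
    return float(logsumexp(f))


# ---------------------------------------------------------------------------
# chain prior (admixture Markov chains with gamma integrated out)
# ---------------------------------------------------------------------------

def betabinom_log_factor(xi, two_n: int, alpha_r) -> np.ndarray:
    """Per-SNP log factor from integrating the admixture rate gamma_j.

    log[ Gamma(xi + ar) Gamma(2N - xi + 1 - ar) / (Gamma(2N+1) Gamma(ar)
    Gamma(1 - ar)) ] with ar = alpha * r_j in (0, 1).
    """
    xi = np.asarray(xi, dtype=float)
    ar = np.asarray(alpha_r, dtype=float)
    if np.any(xi > two_n) or np.any(xi < 0):
        raise ValueError("event counts must lie in [0, 2N]")
    if np.any((ar <= 0) | (ar >= 1)):
        raise ValueError("alpha * r_j must lie in (0, 1)")
    return (gammaln(xi + ar) + gammaln(two_n - xi + 1.0 - ar)
            - gammaln(two_n + 1.0) - gammaln(ar) - gammaln(1.0 - ar))


def chain_prior_logprob(Q, I, sticks: StickWeights, alpha, r) -> float:
    """Log Pr(Q, I | v): stick terms plus marginalized Beta-binomial factors.

    Q and I are (2N, L); I[:, 0] is ignored (chain starts are priced by the
    initial stick term). Requires Q/I consistency: a label change without
    I = 1 has probability zero.
    """
    Q = np.asarray(Q)
    I = np.asarray(I).astype(bool)
    n_chains, L = Q.shape
    if np.any((Q[:, 1:] != Q[:, :-1]) & ~I[:, 1:]):
        raise ValueError("population change without an admixture event")
    v_full = sticks.full()
    logv = np.log(np.where(v_full > 0, v_full, 1.0))
    total = logv[Q[:, 0]].sum()
    if np.any(v_full[Q[:, 0]] <= 0):
        return -np.inf
    ev = I[:, 1:]
    total += logv[Q[:, 1:][ev]].sum()
    if np.any(v_full[Q[:, 1:][ev]] <= 0):
        return -np.inf
    xi = ev.sum(axis=0)
    ar = alpha * np.asarray(r, dtype=float)[1:]
    total += betabinom_log_factor(xi, n_chains, ar).sum()
    return float(total)


def transition_row(gamma: float, sticks: StickWeights, current: int) -> np.ndarray:
    """One row of the heterogeneous transition matrix diag(1-g) + g 1 v'.

    Row entries over occupied labels plus the super state: stay with
    probability (1 - gamma) + gamma * v_current; move to q with
    gamma * v_q; the super state receives gamma * super_mass.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    row = gamma * sticks.full()
    row[current] += 1.0 - gamma
    return row
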