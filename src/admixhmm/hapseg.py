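"""Haplotype segmentation: the first model layer.

Haplotypes (given, or latent behind Poisson read counts) are modelled by
2N Markov chains over an unbounded set of *haplotype states* -- ancestral
haplotype clusters with per-SNP Bernoulli allele frequencies. Chains switch
state with per-SNP recombination probabilities; a stick-breaking prior over
states lets the number of states grow with the data, with all unused states
collapsed into a "super" state. The fitted structure (states S, transition
indicators Phi, per-SNP recombination probabilities r_j, and called
haplotypes H when the input is read counts) is what the admixture layer
consumes: segments of constant state are the units whose population-specific
frequencies carry the ancestry signal, and SNPs where both of an
individual's chains recombine are the candidate phasing switch-error sites.

Fitting is an explicit-parameter blocked Gibbs sampler: each sweep refreshes
the add-one-smoothed emission tables, samples the per-SNP switch rates from
their Beta posteriors and the stick weights from their posterior, then
redraws all chains by forward-filtering/backward-sampling (vectorized across
chains, or across individuals over joint diploid state pairs when genotype
likelihoods couple the two chains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .model import ResidualStick, update_stick_posterior

MEAN_FLOOR = 1e-6  # floor on Poisson means and recombination probabilities


@dataclass
class ReadCountMatrix:
    """Per-individual per-SNP read counts (major, minor) = (ref, alt)."""

    counts: np.ndarray  # (N, L, 2) non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[2] != 2:
            raise ValueError("counts must have shape (N, L, 2)")
        if np.any(c < 0):
            raise ValueError("read counts must be >= 0")
        self.counts = c

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]


@dataclass
class HaplotypeStructure:
    """Output of the segmentation layer.

    ``states``: (2N, L) haplotype-state indices (dense 0..K-1); chain
    2*i + l is haplotype l of individual i. ``transitions``: (2N, L)
    recombination-event indicators (entry j marks an event between SNPs j-1
    and j; column 0 is False). ``recomb_prob``: per-SNP posterior mean
    transition frequency r_j, floored at 1e-6 (r_0 = 0, chain start).
    ``haplotypes``: called alleles when inferred from read counts, else the
    input haplotypes.
    """

    states: np.ndarray
    transitions: np.ndarray
    recomb_prob: np.ndarray
    haplotypes: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.states.shape[0]

    @property
    def n_snps(self) -> int:
        return self.states.shape[1]

    @property
    def genotypes(self) -> np.ndarray:
        """Minor-allele dosage matrix (N, L) from the haplotype calls."""
        if self.haplotypes is None:
            raise ValueError("no haplotypes available")
        h = self.haplotypes
        return h[0::2] + h[1::2]


@dataclass
class SegmentSet:
    """Segments of constant haplotype state, plus double-recombination sites.

    ``chain_starts[c]`` holds the start indices of chain c's segments
    (always beginning with 0); segments are consecutive and tile [0, L).
    ``double_recomb[i]`` holds the interior SNPs at which both chains of
    individual i have a transition event -- the candidate phasing
    switch-error sites (SNP 0 and SNP L-1 are treated as implicit sites
    bounding the first and last block).
    """

    chain_starts: list[np.ndarray]
    double_recomb: list[np.ndarray]
    n_snps: int

    @property
    def n_chains(self) -> int:
        return len(self.chain_starts)

    def segments(self, chain: int) -> list[tuple[int, int]]:
        """Inclusive (a, b) bounds of the chain's segments."""
        starts = self.chain_starts[chain]
        bounds = np.append(starts, self.n_snps)
        return [(int(bounds[k]), int(bounds[k + 1]) - 1) for k in range(starts.size)]

    def blocks(self, individual: int) -> list[tuple[int, int]]:
        """Inclusive spans between consecutive double-recombination sites."""
        sites = [0] + [int(s) for s in self.double_recomb[individual]] + [self.n_snps]
        return [(sites[m], sites[m + 1] - 1) for m in range(len(sites) - 1)]


def segments_from_structure(hs: HaplotypeStructure) -> SegmentSet:
    """Extract maximal constant-state runs and double-recombination sites."""
    S, phi = hs.states, hs.transitions
    n_chains, L = S.shape
    starts = []
    for c in range(n_chains):
        change = np.flatnonzero(S[c, 1:] != S[c, :-1]) + 1
        starts.append(np.concatenate([[0], change]).astype(np.int64))
    double = []
    for i in range(n_chains // 2):
        both = np.flatnonzero(phi[2 * i] & phi[2 * i + 1])
        double.append(both[(both > 0) & (both < L)].astype(np.int64))
    return SegmentSet(chain_starts=starts, double_recomb=double, n_snps=L)


def read_likelihood(d, g: int, coverage: float) -> float:
    """Log-likelihood of a (major, minor) read-count pair given dosage g.

    Product of two Poisson pmfs with means coverage*(2-g)/2 and
    coverage*g/2 (floored at a small epsilon so zero means stay in the
    support).
    """
    major, minor = d
    if major < 0 or minor < 0:
        raise ValueError("read counts must be >= 0")
    mu_minor = max(coverage * g / 2.0, MEAN_FLOOR)
    mu_major = max(coverage * (2 - g) / 2.0, MEAN_FLOOR)
    ll = (minor * np.log(mu_minor) - mu_minor - gammaln(minor + 1)
          + major * np.log(mu_major) - mu_major - gammaln(major + 1))
    return float(ll)


@dataclass
class HapsegConfig:
    """Sampler settings for the segmentation layer.

    ``base_rate`` is the prior recombination level r0: the per-SNP switch
    probability carries a Beta(alpha*r0, 1-alpha*r0) prior, and the first
    ``n_anneal`` burn-in sweeps hold the rate at r0 so that chains can move
    before any transitions have been observed. ``coverage`` is the mean
    sequencing depth for read-count input (estimated from the data when
    None).
    """

    n_burnin: int = 10
    n_samples: int = 10
    alpha: float = 0.2
    base_rate: float = 0.05
    n_anneal: int = 3
    n_random_splits: int = 3
    max_states: int = 40
    coverage: float | None = None
    seed: int = 0


def _categorical_rows(weights: np.ndarray, rng) -> np.ndarray:
    """One categorical draw per row of a non-negative weight matrix."""
    cs = np.cumsum(weights, axis=-1)
    tot = cs[..., -1:]
    r = rng.random(weights.shape[:-1])[..., None] * tot
    return (cs < r).sum(axis=-1)


def _split_state(S: np.ndarray, phi: np.ndarray, q_star: int, rng) -> int:
    """Relabel a random subset of one state's runs to a fresh state.

    Runs are maximal intervals of constant label within a chain; run
    boundaries coincide with transition events (or chain starts), so the
    relabeling keeps the event indicators consistent. Returns the new
    number of states.
    """
    n_chains, L = S.shape
    occupied, counts = np.unique(S, return_counts=True)
    target = occupied[_categorical_rows(counts[None, :].astype(float), rng)[0]]
    fresh = q_star
    moved = False
    for c in range(n_chains):
        row = S[c]
        bounds = np.flatnonzero(np.diff(row) != 0) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [L]])
        for a, b in zip(starts, ends):
            if row[a] == target and rng.random() < 0.5:
                row[a:b] = fresh
                moved = True
    return q_star + 1 if moved else q_star


def _compact_labels(S: np.ndarray) -> int:
    """Relabel states to a dense 0..K-1 range in place; returns K."""
    uniq, inv = np.unique(S, return_inverse=True)
    S[...] = inv.reshape(S.shape)
    return uniq.size


def infer_haplotype_structure(data, config: HapsegConfig | None = None) -> HaplotypeStructure:
    """Fit the segmentation layer to haplotypes or read counts.

    ``data`` is either a (2N, L) binary haplotype matrix (phased input: the
    Poisson read layer is skipped and H is taken as given) or a
    ReadCountMatrix / (N, L, 2) array of per-allele read counts, in which
    case genotypes and haplotypes are called jointly with the states.
    """
    cfg = config or HapsegConfig()
    if isinstance(data, ReadCountMatrix):
        return _fit_from_reads(data.counts, cfg)
    arr = np.asarray(data)
    if arr.ndim == 3:
        return _fit_from_reads(arr, cfg)
    if arr.ndim != 2:
        raise ValueError("data must be (2N, L) haplotypes or (N, L, 2) read counts")
    if arr.shape[1] < 2:
        raise ValueError("need at least two SNPs")
    if arr.shape[0] % 2:
        raise ValueError("haplotype matrix must have an even number of rows")
    return _fit_from_haplotypes(arr.astype(np.int8), cfg)


def _sweep_params(S, phi, H, eta_prior_a, eta_prior_b, cfg, sweep, rng):
    """Refresh emission tables, switch rates and stick weights."""
    n_chains, L = S.shape
    q_star = int(S.max()) + 1
    ones = np.zeros((q_star, L))
    tot = np.zeros((q_star, L))
    cols = np.broadcast_to(np.arange(L), S.shape)
    np.add.at(tot, (S, cols), 1.0)
    np.add.at(ones, (S, cols), H.astype(float))
    theta = (ones + 1.0) / (tot + 2.0)
    # per-SNP switch probability
    if sweep < cfg.n_anneal:
        eta = np.full(L, cfg.base_rate)
    else:
        t_j = phi.sum(axis=0).astype(float)
        eta = rng.beta(eta_prior_a + t_j, eta_prior_b + n_chains - t_j)
        eta = np.clip(eta, MEAN_FLOOR, 1.0 - MEAN_FLOOR)
    eta[0] = 0.0
    # stick weights over states from event/start occupancy
    c = np.zeros(q_star)
    ev = phi.copy()
    ev[:, 0] = True
    np.add.at(c, S[ev], 1.0)
    sticks = update_stick_posterior(c, rng)
    return theta, eta, sticks, q_star


def _fit_from_haplotypes(H: np.ndarray, cfg: HapsegConfig) -> HaplotypeStructure:
    rng = np.random.default_rng(cfg.seed)
    n_chains, L = H.shape
    S = np.zeros((n_chains, L), dtype=np.int64)
    phi = np.zeros((n_chains, L), dtype=bool)
    ea = cfg.alpha * cfg.base_rate
    eb = 1.0 - ea
    n_total = cfg.n_burnin + cfg.n_samples
    split_at = set(np.linspace(0, max(cfg.n_burnin - 1, 1), cfg.n_random_splits,
                               dtype=int).tolist()) if cfg.n_random_splits else set()
    acc_states = None
    acc_trans = np.zeros(L)
    n_acc = 0

    for sweep in range(n_total):
        q_star = _compact_labels(S)
        if sweep in split_at and sweep < cfg.n_burnin and q_star < cfg.max_states:
            _split_state(S, phi, q_star, rng)
            q_star = _compact_labels(S)
        theta, eta, sticks, q_star = _sweep_params(S, phi, H,
                                                   ea, eb, cfg, sweep, rng)
        allow_super = q_star < cfg.max_states
        P = q_star + (1 if allow_super else 0)
        u = sticks.full() if allow_super else sticks.v / sticks.v.sum()
        log_t1 = np.log(theta)          # (q*, L)
        log_t0 = np.log1p(-theta)
        # forward filtering, vectorized over chains
        M = np.empty((L, n_chains, P))
        Hf = H.astype(bool)
        for j in range(L):
            e1 = log_t1[:, j]
            e0 = log_t0[:, j]
            if allow_super:
                e1 = np.append(e1, np.log(0.5))
                e0 = np.append(e0, np.log(0.5))
            logE = np.where(Hf[:, j, None], e1[None, :], e0[None, :])
            E = np.exp(logE - logE.max(axis=1, keepdims=True))
            if j == 0:
                m = u[None, :] * E
            else:
                prev = M[j - 1]
                m = ((1.0 - eta[j]) * prev
                     + eta[j] * prev.sum(axis=1, keepdims=True) * u[None, :]) * E
            M[j] = m / m.sum(axis=1, keepdims=True)
        # backward sampling
        s = _categorical_rows(M[L - 1], rng)
        S[:, L - 1] = s
        for j in range(L - 2, -1, -1):
            prev = M[j]
            u_next = u[s]
            stay = (1.0 - eta[j + 1]) * prev[np.arange(n_chains), s]
            redraw = eta[j + 1] * u_next * prev.sum(axis=1)
            event = rng.random(n_chains) * (stay + redraw) < redraw
            phi[:, j + 1] = event
            s_prev = s.copy()
            if event.any():
                s_prev[event] = _categorical_rows(prev[event], rng)
            S[:, j] = s_prev
            s = s_prev
        phi[:, 0] = False
        if allow_super:
            residual = ResidualStick(q_star, rng)
            _relabel_super(S, phi, q_star, residual)
        if sweep >= cfg.n_burnin:
            q_now = int(S.max()) + 1
            if acc_states is None or acc_states.shape[2] < max(q_now, 1):
                new = np.zeros((n_chains, L, max(q_now, cfg.max_states)), dtype=np.uint16)
                if acc_states is not None:
                    new[:, :, : acc_states.shape[2]] = acc_states
                acc_states = new
            cols = np.broadcast_to(np.arange(L), S.shape)
            np.add.at(acc_states, (np.arange(n_chains)[:, None], cols, S), 1)
            acc_trans += phi.sum(axis=0) / n_chains
            n_acc += 1

    return _finalize(acc_states, acc_trans, n_acc, H)


def _relabel_super(S, phi, super_idx, residual: ResidualStick):
    """Give concrete labels to super-state visits after a backward pass.

    A fresh label is drawn at the start of each super run and wherever a
    transition event lands on the super state again within a run (a redraw
    onto another unoccupied state).
    """
    for c in range(S.shape[0]):
        idx = np.flatnonzero(S[c] == super_idx)
        if idx.size == 0:
            continue
        label = -1
        prev_j = -2
        for j in idx:
            if j != prev_j + 1 or phi[c, j] or label < 0:
                label = residual.sample()
            S[c, j] = label
            prev_j = j


def _finalize(acc_states, acc_trans, n_acc, H) -> HaplotypeStructure:
    n_chains, L = H.shape
    if acc_states is None:  # no sampling sweeps configured
        raise ValueError("sampler collected no posterior draws")
    S_map = np.argmax(acc_states, axis=2).astype(np.int64)
    _compact_labels(S_map)
    trans_freq = acc_trans / n_acc
    phi_map = np.zeros((n_chains, L), dtype=bool)
    phi_map[:, 1:] = S_map[:, 1:] != S_map[:, :-1]
    r = np.maximum(trans_freq, MEAN_FLOOR)
    r = np.minimum(r, 1.0 - MEAN_FLOOR)
    r[0] = 0.0
    return HaplotypeStructure(states=S_map, transitions=phi_map,
                              recomb_prob=r, haplotypes=H.copy())


# ---------------------------------------------------------------------------
# read-count (genotype) mode: joint diploid chains
# ---------------------------------------------------------------------------

def _fit_from_reads(counts: np.ndarray, cfg: HapsegConfig) -> HaplotypeStructure:
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    N, L, _ = counts.shape
    if L < 2:
        raise ValueError("need at least two SNPs")
    n_chains = 2 * N
    coverage = cfg.coverage or float(counts.sum(axis=2).mean())
    # log Poisson likelihood of each dosage at each (individual, SNP)
    major, minor = counts[..., 0], counts[..., 1]
    logpois = np.empty((N, L, 3))
    for g in range(3):
        mu_min = max(coverage * g / 2.0, MEAN_FLOOR)
        mu_maj = max(coverage * (2 - g) / 2.0, MEAN_FLOOR)
        logpois[..., g] = (minor * np.log(mu_min) - mu_min - gammaln(minor + 1)
                           + major * np.log(mu_maj) - mu_maj - gammaln(major + 1))
    # initial haplotype calls from the marginal genotype likelihood
    g0 = np.argmax(logpois, axis=2)
    H = np.zeros((n_chains, L), dtype=np.int8)
    het_flip = rng.random((N, L)) < 0.5
    H[0::2] = (g0 == 2) | ((g0 == 1) & het_flip)
    H[1::2] = (g0 == 2) | ((g0 == 1) & ~het_flip)
    S = np.zeros((n_chains, L), dtype=np.int64)
    phi = np.zeros((n_chains, L), dtype=bool)
    ea = cfg.alpha * cfg.base_rate
    eb = 1.0 - ea
    n_total = cfg.n_burnin + cfg.n_samples
    split_at = set(np.linspace(0, max(cfg.n_burnin - 1, 1), cfg.n_random_splits,
                               dtype=int).tolist()) if cfg.n_random_splits else set()
    acc_states = None
    acc_trans = np.zeros(L)
    acc_hap = np.zeros((n_chains, L))
    acc_geno = np.zeros((N, L, 3))
    n_acc = 0
    lik = np.exp(logpois - logpois.max(axis=2, keepdims=True))  # (N, L, 3)

    for sweep in range(n_total):
        q_star = _compact_labels(S)
        if sweep in split_at and sweep < cfg.n_burnin and q_star < cfg.max_states:
            _split_state(S, phi, q_star, rng)
            q_star = _compact_labels(S)
        theta, eta, sticks, q_star = _sweep_params(S, phi, H, ea, eb, cfg, sweep, rng)
        allow_super = q_star < cfg.max_states
        P = q_star + (1 if allow_super else 0)
        u = sticks.full() if allow_super else sticks.v / sticks.v.sum()
        m_full = np.append(theta, np.full((1, L), 0.5), axis=0) if allow_super else theta
        # forward over joint diploid pairs, vectorized over individuals
        M = np.empty((L, N, P, P))
        for j in range(L):
            m = m_full[:, j]
            o0 = np.outer(1 - m, 1 - m)
            o1 = np.outer(m, 1 - m) + np.outer(1 - m, m)
            o2 = np.outer(m, m)
            E = (lik[:, j, 0, None, None] * o0
                 + lik[:, j, 1, None, None] * o1
                 + lik[:, j, 2, None, None] * o2)
            if j == 0:
                mm = (u[:, None] * u[None, :])[None, :, :] * E
            else:
                prev = M[j - 1]
                h = eta[j]
                row = prev.sum(axis=1)          # marginal over s1 -> (N, P)
                col = prev.sum(axis=2)          # marginal over s2 -> (N, P)
                tot = row.sum(axis=1)
                mm = ((1 - h) ** 2 * prev
                      + (1 - h) * h * (col[:, :, None] * u[None, None, :])
                      + h * (1 - h) * (u[None, :, None] * row[:, None, :])
                      + h * h * tot[:, None, None] * (u[:, None] * u[None, :])[None])
                mm = mm * E
            M[j] = mm / mm.sum(axis=(1, 2), keepdims=True)
        # backward sampling of pairs
        flat = M[L - 1].reshape(N, -1)
        cell = _categorical_rows(flat, rng)
        s1, s2 = cell // P, cell % P
        S[0::2, L - 1], S[1::2, L - 1] = s1, s2
        iN = np.arange(N)
        for j in range(L - 2, -1, -1):
            prev = M[j]
            h = eta[j + 1]
            t1 = np.full((N, P), h) * u[s1][:, None]
            t1[iN, s1] += 1 - h
            t2 = np.full((N, P), h) * u[s2][:, None]
            t2[iN, s2] += 1 - h
            W = prev * t1[:, :, None] * t2[:, None, :]
            cell = _categorical_rows(W.reshape(N, -1), rng)
            p1, p2 = cell // P, cell % P
            for (pc, sc, off) in ((p1, s1, 0), (p2, s2, 1)):
                moved = pc != sc
                stay_ev = h * u[sc] / ((1 - h) + h * u[sc])
                phi[off::2, j + 1] = moved | (rng.random(N) < stay_ev)
            S[0::2, j], S[1::2, j] = p1, p2
            s1, s2 = p1, p2
        phi[:, 0] = False
        if allow_super:
            residual = ResidualStick(q_star, rng)
            _relabel_super(S, phi, q_star, residual)
        # resample haplotypes given states and reads
        q_now = int(S.max()) + 1
        ones = np.zeros((q_now, L))
        tot = np.zeros((q_now, L))
        cols2 = np.broadcast_to(np.arange(L), S.shape)
        np.add.at(tot, (S, cols2), 1.0)
        np.add.at(ones, (S, cols2), H.astype(float))
        th = (ones + 1.0) / (tot + 2.0)
        a1 = th[S[0::2], np.arange(L)[None, :]]
        a2 = th[S[1::2], np.arange(L)[None, :]]
        w = np.stack([
            (1 - a1) * (1 - a2) * lik[:, :, 0],
            (1 - a1) * a2 * lik[:, :, 1],
            a1 * (1 - a2) * lik[:, :, 1],
            a1 * a2 * lik[:, :, 2],
        ], axis=-1)
        combo = _categorical_rows(w, rng)
        H[0::2] = (combo >= 2).astype(np.int8)
        H[1::2] = (combo % 2).astype(np.int8)
        if sweep >= cfg.n_burnin:
            if acc_states is None or acc_states.shape[2] < q_now:
                new = np.zeros((n_chains, L, max(q_now, cfg.max_states)), dtype=np.uint16)
                if acc_states is not None:
                    new[:, :, : acc_states.shape[2]] = acc_states
                acc_states = new
            np.add.at(acc_states, (np.arange(n_chains)[:, None], cols2, S), 1)
            acc_trans += phi.sum(axis=0) / n_chains
            acc_hap += H
            acc_geno[iN[:, None], np.arange(L)[None, :], H[0::2] + H[1::2]] += 1
            n_acc += 1

    hs = _finalize(acc_states, acc_trans, n_acc, H)
    g_map = np.argmax(acc_geno, axis=2)
    H_map = np.zeros((n_chains, L), dtype=np.int8)
    hap_frac = acc_hap / n_acc
    H_map[0::2] = (hap_frac[0::2] > 0.5) & (g_map > 0) | (g_map == 2)
    H_map[1::2] = (g_map - H_map[0::2]).clip(0, 1).astype(np.int8)
    hs.haplotypes = H_map
    return hs
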