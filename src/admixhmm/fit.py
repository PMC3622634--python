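"""Model fitting: collapsed per-individual forward-summation/backward-sampling.

Each sweep updates one individual at a time, conditioning on every other
individual's population chains. The update runs over the joint diploid +
switch-error state (q1, q2, delta): q1, q2 range over the currently occupied
populations plus the collapsed "super" state holding all unoccupied labels,
and delta is the phasing switch state, flipping only at the individual's
double-recombination sites. Population redraws are restricted to the
individual's haplotype segment boundaries; the per-SNP admixture rate
gamma_j is integrated out, leaving the sequential Beta-Bernoulli predictive
for the pair of chains given the event counts of the other chains:

    P(I1 = 1) = (xi_j^(-i) + alpha r_j) / (2N - 1)
    P(I2 = 1 | I1) = (xi_j^(-i) + I1 + alpha r_j) / 2N

Because nothing changes between consecutive "event" positions (segment
starts of either chain and double-recombination sites), the recursion runs
over events only, with per-interval emission log-sums accumulated in
advance. After the backward pass, super-state selections are converted to
concrete fresh labels drawn from the residual stick. Burn-in interleaves
random population splits to escape local modes; posterior samples yield
per-SNP maximum-a-posteriori labels, label frequencies, the inferred number
of populations per SNP, and per-SNP admixture-event rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .hapseg import HaplotypeStructure, SegmentSet, segments_from_structure
from .model import (DEFAULT_ALPHA, DEFAULT_EPSILON, ResidualStick,
                    build_chain_weights, compact_states, update_emission_table,
                    update_stick_posterior)


@dataclass
class FitConfig:
    """Settings for the admixture-layer sampler.

    ``mode`` selects backward sampling (default; helps escape local modes)
    or backward maximization. ``fixed_K`` switches to the finite
    heterogeneous Markov model with C populations (used with reference
    individuals, or alone for the "0 ref" setting); the stick prior is then
    replaced by a symmetric Dirichlet(1, ..., 1).
    """

    n_burnin: int = 20
    n_samples: int = 30
    mode: str = "sample"
    n_random_splits: int = 3
    seed: int = 0
    fixed_K: int | None = None
    epsilon: float = DEFAULT_EPSILON
    alpha: float = DEFAULT_ALPHA
    weight_scheme: str = "segment_mean"
    max_pops: int = 30
    anneal_start: float = 0.1

    def __post_init__(self):
        if self.n_burnin < 0 or self.n_samples < 1:
            raise ValueError("need n_samples >= 1 and n_burnin >= 0")
        if self.mode not in ("sample", "maximize"):
            raise ValueError("mode must be 'sample' or 'maximize'")
        if self.fixed_K is not None and self.fixed_K < 1:
            raise ValueError("fixed_K must be >= 1 when set")
        if not 0.0 < self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in (0, 0.5]")


@dataclass
class PosteriorSummary:
    """Per-SNP posterior summaries of the admixture fit.

    ``map_labels``: (2N, L) maximum-a-posteriori population label per
    haplotype per SNP (dense 0-based labels, ordered by first appearance
    along the genome). ``label_freq``: posterior label frequencies, summing
    to 1 over the label axis. ``n_pops_map``: per-SNP MAP number of
    distinct populations. ``admix_rate``: posterior mean per-SNP
    admixture-event rate (events per chain).
    """

    map_labels: np.ndarray
    label_freq: np.ndarray
    n_pops_map: np.ndarray
    admix_rate: np.ndarray
    n_sweeps: int

    @property
    def n_chains(self) -> int:
        return self.map_labels.shape[0]


# ---------------------------------------------------------------------------
# numba kernels over the (q1, q2, delta) product space at event resolution
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel_forward(r1, r2, fl, E, g1, g2a, g2b, v, eps, M):
    """Forward summation; fills normalized messages M (T,P,P,2), returns loglik."""
    T = E.shape[0]
    P = v.shape[0]
    loglik = 0.0
    tmp = np.empty((P, P, 2))
    for t in range(T):
        if t == 0:
            for a in range(P):
                for b in range(P):
                    tmp[a, b, 0] = v[a] * v[b] * (1.0 - eps)
                    tmp[a, b, 1] = v[a] * v[b] * eps
        else:
            prev = M[t - 1]
            sum1 = np.zeros((P, 2))  # marginal over q1 -> indexed by q2
            sum2 = np.zeros((P, 2))  # marginal over q2 -> indexed by q1
            tot = np.zeros(2)
            for a in range(P):
                for b in range(P):
                    for d in range(2):
                        x = prev[a, b, d]
                        sum1[b, d] += x
                        sum2[a, d] += x
                        tot[d] += x
            a1 = r1[t]
            a2 = r2[t]
            if a1 and a2:
                p00 = (1.0 - g1[t]) * (1.0 - g2a[t])
                p01 = (1.0 - g1[t]) * g2a[t]
                p10 = g1[t] * (1.0 - g2b[t])
                p11 = g1[t] * g2b[t]
                for a in range(P):
                    for b in range(P):
                        for d in range(2):
                            tmp[a, b, d] = (p00 * prev[a, b, d]
                                            + p01 * sum2[a, d] * v[b]
                                            + p10 * v[a] * sum1[b, d]
                                            + p11 * tot[d] * v[a] * v[b])
            elif a1:
                for a in range(P):
                    for b in range(P):
                        for d in range(2):
                            tmp[a, b, d] = ((1.0 - g1[t]) * prev[a, b, d]
                                            + g1[t] * v[a] * sum1[b, d])
            elif a2:
                for a in range(P):
                    for b in range(P):
                        for d in range(2):
                            tmp[a, b, d] = ((1.0 - g2a[t]) * prev[a, b, d]
                                            + g2a[t] * sum2[a, d] * v[b])
            else:
                for a in range(P):
                    for b in range(P):
                        for d in range(2):
                            tmp[a, b, d] = prev[a, b, d]
            if fl[t]:
                for a in range(P):
                    for b in range(P):
                        m0 = tmp[a, b, 0]
                        m1 = tmp[a, b, 1]
                        tmp[a, b, 0] = (1.0 - eps) * m0 + eps * m1
                        tmp[a, b, 1] = eps * m0 + (1.0 - eps) * m1
        # emission for interval t
        maxe = -1e308
        for a in range(P):
            for b in range(P):
                if tmp[a, b, 0] > 0.0 or tmp[a, b, 1] > 0.0:
                    e0 = E[t, 0, a] + E[t, 1, b]
                    e1 = E[t, 1, a] + E[t, 0, b]
                    if tmp[a, b, 0] > 0.0 and e0 > maxe:
                        maxe = e0
                    if tmp[a, b, 1] > 0.0 and e1 > maxe:
                        maxe = e1
        s = 0.0
        for a in range(P):
            for b in range(P):
                e0 = np.exp(E[t, 0, a] + E[t, 1, b] - maxe)
                e1 = np.exp(E[t, 1, a] + E[t, 0, b] - maxe)
                m0 = tmp[a, b, 0] * e0
                m1 = tmp[a, b, 1] * e1
                M[t, a, b, 0] = m0
                M[t, a, b, 1] = m1
                s += m0 + m1
        for a in range(P):
            for b in range(P):
                M[t, a, b, 0] /= s
                M[t, a, b, 1] /= s
        loglik += maxe + np.log(s)
    return loglik


@njit(cache=True)
def _kernel_backward_sample(r1, r2, fl, g1, g2a, g2b, v, eps, M, urand,
                            q1o, q2o, do, i1o, i2o):
    """Backward sampling of (q1, q2, delta) and event indicators per event."""
    T = M.shape[0]
    P = M.shape[1]
    # sample final cell (dedicated uniform: the loop reuses column 0 at T-1)
    r = urand[T - 1, 2]
    acc = 0.0
    a_c = 0
    b_c = 0
    d_c = 0
    done = False
    for a in range(P):
        for b in range(P):
            for d in range(2):
                acc += M[T - 1, a, b, d]
                if not done and r < acc:
                    a_c, b_c, d_c = a, b, d
                    done = True
    q1o[T - 1] = a_c
    q2o[T - 1] = b_c
    do[T - 1] = d_c
    W = np.empty((P, P, 2))
    for t in range(T - 1, 0, -1):
        a1 = r1[t]
        a2 = r2[t]
        if a1 and a2:
            p00 = (1.0 - g1[t]) * (1.0 - g2a[t])
            p01 = (1.0 - g1[t]) * g2a[t]
            p10 = g1[t] * (1.0 - g2b[t])
            p11 = g1[t] * g2b[t]
        elif a1:
            p00 = 1.0 - g1[t]
            p01 = 0.0
            p10 = g1[t]
            p11 = 0.0
        elif a2:
            p00 = 1.0 - g2a[t]
            p01 = g2a[t]
            p10 = 0.0
            p11 = 0.0
        else:
            p00 = 1.0
            p01 = 0.0
            p10 = 0.0
            p11 = 0.0
        # case weights: (I1, I2) -> chain factor given previous cell (a, b)
        tot_w = 0.0
        for a in range(P):
            for b in range(P):
                if a1 and a2:
                    w = p11 * v[a_c] * v[b_c]
                    if a == a_c:
                        w += p01 * v[b_c]
                    if b == b_c:
                        w += p10 * v[a_c]
                    if a == a_c and b == b_c:
                        w += p00
                elif a1:
                    w = (g1[t] * v[a_c]) if b == b_c else 0.0
                    if a == a_c and b == b_c:
                        w += 1.0 - g1[t]
                elif a2:
                    w = (g2a[t] * v[b_c]) if a == a_c else 0.0
                    if a == a_c and b == b_c:
                        w += 1.0 - g2a[t]
                else:
                    w = 1.0 if (a == a_c and b == b_c) else 0.0
                for d in range(2):
                    if fl[t]:
                        kd = (1.0 - eps) if d == d_c else eps
                    else:
                        kd = 1.0 if d == d_c else 0.0
                    W[a, b, d] = M[t - 1, a, b, d] * w * kd
                    tot_w += W[a, b, d]
        r = urand[t, 0] * tot_w
        acc = 0.0
        a_p = 0
        b_p = 0
        d_p = 0
        done = False
        for a in range(P):
            for b in range(P):
                for d in range(2):
                    acc += W[a, b, d]
                    if not done and r < acc:
                        a_p, b_p, d_p = a, b, d
                        done = True
        # event indicators for the transition into event t
        c00 = p00 if (a_p == a_c and b_p == b_c) else 0.0
        c01 = p01 * v[b_c] if a_p == a_c else 0.0
        c10 = p10 * v[a_c] if b_p == b_c else 0.0
        c11 = p11 * v[a_c] * v[b_c]
        ctot = c00 + c01 + c10 + c11
        rc = urand[t, 1] * ctot
        if rc < c00:
            i1o[t] = 0
            i2o[t] = 0
        elif rc < c00 + c01:
            i1o[t] = 0
            i2o[t] = 1
        elif rc < c00 + c01 + c10:
            i1o[t] = 1
            i2o[t] = 0
        else:
            i1o[t] = 1
            i2o[t] = 1
        q1o[t - 1] = a_p
        q2o[t - 1] = b_p
        do[t - 1] = d_p
        a_c, b_c, d_c = a_p, b_p, d_p
    i1o[0] = 0
    i2o[0] = 0


@njit(cache=True)
def _kernel_viterbi(r1, r2, fl, E, g1, g2a, g2b, v, eps,
                    q1o, q2o, do, i1o, i2o):
    """Joint MAP path over (Q, I, delta); lowest-index tie-breaking."""
    T = E.shape[0]
    P = v.shape[0]
    n_cells = P * P * 2
    logM = np.empty((T, n_cells))
    back = np.empty((T, n_cells), dtype=np.int64)
    case = np.empty((T, n_cells), dtype=np.int64)
    NEG = -1e308
    for a in range(P):
        for b in range(P):
            for d in range(2):
                c = (a * P + b) * 2 + d
                pd = (1.0 - eps) if d == 0 else eps
                pv = v[a] * v[b] * pd
                e = (E[0, 0, a] + E[0, 1, b]) if d == 0 else (E[0, 1, a] + E[0, 0, b])
                logM[0, c] = (np.log(pv) + e) if pv > 0.0 else NEG
                back[0, c] = -1
                case[0, c] = 0
    for t in range(1, T):
        a1 = r1[t]
        a2 = r2[t]
        if a1 and a2:
            p00 = (1.0 - g1[t]) * (1.0 - g2a[t])
            p01 = (1.0 - g1[t]) * g2a[t]
            p10 = g1[t] * (1.0 - g2b[t])
            p11 = g1[t] * g2b[t]
        elif a1:
            p00 = 1.0 - g1[t]
            p01 = 0.0
            p10 = g1[t]
            p11 = 0.0
        elif a2:
            p00 = 1.0 - g2a[t]
            p01 = g2a[t]
            p10 = 0.0
            p11 = 0.0
        else:
            p00 = 1.0
            p01 = 0.0
            p10 = 0.0
            p11 = 0.0
        for ac in range(P):
            for bc in range(P):
                for dc in range(2):
                    cc = (ac * P + bc) * 2 + dc
                    best = NEG
                    best_prev = -1
                    best_case = 0
                    e = (E[t, 0, ac] + E[t, 1, bc]) if dc == 0 else (E[t, 1, ac] + E[t, 0, bc])
                    for ap in range(P):
                        for bp in range(P):
                            for dp in range(2):
                                cp = (ap * P + bp) * 2 + dp
                                if logM[t - 1, cp] < -1e307:
                                    continue
                                if fl[t]:
                                    kd = (1.0 - eps) if dp == dc else eps
                                else:
                                    if dp != dc:
                                        continue
                                    kd = 1.0
                                # max over admissible (I1, I2) cases
                                wbest = 0.0
                                kbest = 0
                                if ap == ac and bp == bc and p00 > wbest:
                                    wbest = p00
                                    kbest = 0
                                if ap == ac:
                                    w = p01 * v[bc]
                                    if w > wbest:
                                        wbest = w
                                        kbest = 1
                                if bp == bc:
                                    w = p10 * v[ac]
                                    if w > wbest:
                                        wbest = w
                                        kbest = 2
                                w = p11 * v[ac] * v[bc]
                                if w > wbest:
                                    wbest = w
                                    kbest = 3
                                if wbest <= 0.0 or kd <= 0.0:
                                    continue
                                val = logM[t - 1, cp] + np.log(wbest * kd)
                                if val > best:
                                    best = val
                                    best_prev = cp
                                    best_case = kbest
                    logM[t, cc] = best + e if best_prev >= 0 else NEG
                    back[t, cc] = best_prev
                    case[t, cc] = best_case
    # backtrack from the best (lowest-index on ties) final cell
    best = NEG
    cc = 0
    for c in range(n_cells):
        if logM[T - 1, c] > best:
            best = logM[T - 1, c]
            cc = c
    for t in range(T - 1, -1, -1):
        d = cc % 2
        b = (cc // 2) % P
        a = cc // (2 * P)
        q1o[t] = a
        q2o[t] = b
        do[t] = d
        if t > 0:
            k = case[t, cc]
            i1o[t] = 1 if k >= 2 else 0
            i2o[t] = 1 if (k == 1 or k == 3) else 0
            cc = back[t, cc]
    i1o[0] = 0
    i2o[0] = 0
    return best


# ---------------------------------------------------------------------------
# per-individual event structure and python-facing forward/backward
# ---------------------------------------------------------------------------

@dataclass
class IndividualModel:
    """Everything the forward/backward kernel needs for one individual.

    Event positions are the sorted union of the two chains' segment starts
    and the individual's double-recombination sites (position 0 is the
    chain start). ``E`` holds per-event-interval emission log-sums
    E[t, l, q] = sum over SNPs of w * log Pr(s | q) for chain l; under
    delta = 1 the two rows swap. ``g1``/``g2a``/``g2b`` are the sequential
    pair predictives at each event position; ``v`` includes the super-state
    mass as its last entry in de novo mode.
    """

    ev_pos: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    fl: np.ndarray
    E: np.ndarray
    g1: np.ndarray
    g2a: np.ndarray
    g2b: np.ndarray
    v: np.ndarray
    eps: float

    @property
    def n_events(self) -> int:
        return self.ev_pos.size


def forward_summation(im: IndividualModel) -> tuple[np.ndarray, float]:
    """Normalized forward messages over (q1, q2, delta) and the log-likelihood."""
    T, P = im.n_events, im.v.size
    M = np.empty((T, P, P, 2))
    loglik = _kernel_forward(im.r1, im.r2, im.fl, im.E, im.g1, im.g2a,
                             im.g2b, im.v, im.eps, M)
    return M, float(loglik)


def backward_pass(im: IndividualModel, M: np.ndarray, rng=None,
                  mode: str = "sample"):
    """Sample (or maximize) the event-level path (q1, q2, delta, I1, I2)."""
    T, P = im.n_events, im.v.size
    q1 = np.empty(T, dtype=np.int64)
    q2 = np.empty(T, dtype=np.int64)
    d = np.empty(T, dtype=np.int64)
    i1 = np.zeros(T, dtype=np.int64)
    i2 = np.zeros(T, dtype=np.int64)
    if mode == "sample":
        urand = rng.random((T, 3))
        _kernel_backward_sample(im.r1, im.r2, im.fl, im.g1, im.g2a, im.g2b,
                                im.v, im.eps, M, urand, q1, q2, d, i1, i2)
    else:
        _kernel_viterbi(im.r1, im.r2, im.fl, im.E, im.g1, im.g2a, im.g2b,
                        im.v, im.eps, q1, q2, d, i1, i2)
    return q1, q2, d, i1, i2


# ---------------------------------------------------------------------------
# random splits
# ---------------------------------------------------------------------------

def random_split(Q: np.ndarray, I: np.ndarray, rng: np.random.Generator,
                 fresh_label: int | None = None) -> int:
    """Split one occupied population: relabel a random subset of its runs.

    Runs are maximal constant-label intervals within a chain; their
    boundaries carry admixture events already, so relabeling whole runs
    keeps the (Q, I) invariants intact. Modifies Q in place and returns the
    number of occupied labels afterwards.
    """
    occupied, counts = np.unique(Q, return_counts=True)
    target = rng.choice(occupied, p=counts / counts.sum())
    fresh = int(Q.max()) + 1 if fresh_label is None else fresh_label
    moved = False
    for c in range(Q.shape[0]):
        row = Q[c]
        bounds = np.flatnonzero(np.diff(row) != 0) + 1
        ev = np.flatnonzero(I[c])
        starts = np.unique(np.concatenate([[0], bounds, ev]))
        ends = np.append(starts[1:], Q.shape[1])
        for a, b in zip(starts, ends):
            if row[a] == target and rng.random() < 0.5:
                row[a:b] = fresh
                moved = True
    return int(Q.max()) + 1 if moved else int(np.unique(Q).size)


def _compact_pops(Q: np.ndarray) -> int:
    uniq, inv = np.unique(Q, return_inverse=True)
    Q[...] = inv.reshape(Q.shape)
    return uniq.size


# ---------------------------------------------------------------------------
# the fitting loop
# ---------------------------------------------------------------------------

def _event_structure(segs: SegmentSet, i: int):
    """Sorted event positions and per-event capability flags for individual i."""
    c1, c2 = 2 * i, 2 * i + 1
    s1 = segs.chain_starts[c1]
    s2 = segs.chain_starts[c2]
    dr = segs.double_recomb[i]
    ev_pos = np.unique(np.concatenate([[0], s1, s2, dr]))
    in1 = np.isin(ev_pos, s1)
    in2 = np.isin(ev_pos, s2)
    infl = np.isin(ev_pos, dr)
    r1 = in1.copy()
    r2 = in2.copy()
    r1[0] = r2[0] = False  # position 0 is the chain start, not an event
    infl[0] = False
    return ev_pos, r1, r2, infl


def fit(hapstruct: HaplotypeStructure,
        segs: SegmentSet | None = None,
        ref_labels: np.ndarray | None = None,
        cfg: FitConfig | None = None,
        trace=None) -> PosteriorSummary:
    """Fit the admixture layer to a haplotype structure.

    ``ref_labels`` is an optional (N,) array giving the known population of
    each reference individual and -1 for sample individuals; supplying it
    (or setting ``cfg.fixed_K``) switches to the fixed-C heterogeneous
    Markov model in which reference chains stay pinned to their labels at
    every SNP while still contributing to the emission tables, the event
    counts and the population weights.
    """
    cfg = cfg or FitConfig()
    if segs is None:
        segs = segments_from_structure(hapstruct)
    rng = np.random.default_rng(cfg.seed)
    S = hapstruct.states
    r = hapstruct.recomb_prob
    n_chains, L = S.shape
    N = n_chains // 2
    sid, K = compact_states(S)
    logK = np.log(K.astype(float))
    W = build_chain_weights(segs.chain_starts, L, r, cfg.weight_scheme)
    events = [_event_structure(segs, i) for i in range(N)]

    if ref_labels is not None:
        ref_labels = np.asarray(ref_labels)
        if ref_labels.shape != (N,):
            raise ValueError("ref_labels must have one entry per individual")
        n_ref_pops = int(ref_labels.max()) + 1 if np.any(ref_labels >= 0) else 0
        fixed_K = cfg.fixed_K or n_ref_pops
        if n_ref_pops > fixed_K:
            raise ValueError("reference labels exceed the fixed population count")
    else:
        ref_labels = np.full(N, -1)
        fixed_K = cfg.fixed_K
    is_ref = ref_labels >= 0
    denovo = fixed_K is None

    # initialization: everyone in population 0 without events, then one
    # forced split (de novo); random per-chain labels in the fixed-K model
    Q = np.zeros((n_chains, L), dtype=np.int64)
    I = np.zeros((n_chains, L), dtype=bool)
    if denovo:
        random_split(Q, I, rng)
        q_star = _compact_pops(Q)
    else:
        q_star = fixed_K
        Q[...] = rng.integers(0, fixed_K, size=(n_chains, 1))
    for i in np.flatnonzero(is_ref):
        Q[2 * i] = ref_labels[i]
        Q[2 * i + 1] = ref_labels[i]
        I[2 * i] = False
        I[2 * i + 1] = False

    ar = cfg.alpha * r
    n_total = cfg.n_burnin + cfg.n_samples
    # splits live in the soft (tempered) phase of burn-in so the chain can
    # reorganize -- and re-merge superfluous populations -- while the
    # emission evidence is still weak
    if denovo and cfg.n_random_splits:
        soft_end = max(int(0.75 * cfg.n_burnin) // 2, 1)
        split_at = set(np.linspace(1, soft_end,
                                   cfg.n_random_splits, dtype=int).tolist())
    else:
        split_at = set()
    max_pops = fixed_K if fixed_K is not None else cfg.max_pops

    acc_labels = np.zeros((n_chains, L, max_pops), dtype=np.uint32)
    acc_npop = np.zeros((L, n_chains + 1), dtype=np.uint32)
    acc_rate = np.zeros(L)
    n_acc = 0
    cols = np.arange(L)

    for sweep in range(n_total):
        if denovo:
            q_star = _compact_pops(Q)
            if sweep in split_at and sweep < cfg.n_burnin and q_star < max_pops:
                random_split(Q, I, rng)
                q_star = _compact_pops(Q)
        # population weights
        ev = I.copy()
        ev[:, 0] = True
        c_q = np.bincount(Q[ev], minlength=q_star).astype(float)
        if denovo:
            sticks = update_stick_posterior(c_q, rng)
            allow_super = q_star < max_pops
            if allow_super:
                v_full = sticks.full()
            else:
                v_full = sticks.v / sticks.v.sum()
        else:
            v_full = rng.dirichlet(c_q + 1.0)
            allow_super = False
        P = v_full.size
        # emission table and per-chain per-SNP log Pr(s | q). On the first
        # sweep of a referenced fit the table is built from the reference
        # chains alone: they define the populations, and the randomly
        # initialized sample chains would otherwise swamp their signal and
        # can lock the fit into a label-swapped mode.
        if sweep == 0 and np.any(is_ref):
            ref_chain = np.repeat(is_ref, 2)
            probs = update_emission_table(sid[ref_chain], Q[ref_chain],
                                          q_star, K)
        else:
            probs = update_emission_table(sid, Q, q_star, K)
        logp = np.log(probs[:, sid, cols])        # (q*, 2N, L)
        logP = np.moveaxis(logp, 0, 2)            # (2N, L, q*)
        if allow_super:
            sup = np.broadcast_to(-logK[None, :, None], (n_chains, L, 1))
            logP = np.concatenate([logP, sup], axis=2)
        # burn-in annealing: temper the emission evidence while coarse
        # structure forms, so chains can still move between populations;
        # tau reaches 1 when sampling starts (merging of superfluous
        # sub-clusters is only possible while the evidence is soft, so the
        # ramp spans all of burn-in). With pinned reference individuals the
        # labels are anchored from the first sweep, and tempering would let
        # the majority of free chains lock into a label-swapped mode the
        # few references cannot overturn -- so the ramp only runs in
        # unreferenced fits.
        ramp_end = 0 if np.any(is_ref) else cfg.n_burnin
        if sweep < ramp_end:
            tau = cfg.anneal_start ** (1.0 - sweep / ramp_end)
        else:
            tau = 1.0
        A = tau * W[:, :, None] * logP            # weighted log emissions
        xi = I.sum(axis=0).astype(np.int64)

        residual = ResidualStick(q_star, rng) if allow_super else None
        for i in range(N):
            if is_ref[i]:
                continue
            c1, c2 = 2 * i, 2 * i + 1
            ev_pos, r1, r2, fl = events[i]
            T = ev_pos.size
            xi_minus = xi[ev_pos] - I[c1, ev_pos] - I[c2, ev_pos]
            arj = ar[ev_pos]
            g1 = (xi_minus + arj) / (n_chains - 1)
            g2a = (xi_minus + arj) / n_chains
            g2b = (xi_minus + 1 + arj) / n_chains
            E = np.empty((T, 2, P))
            E[:, 0, :] = np.add.reduceat(A[c1], ev_pos, axis=0)
            E[:, 1, :] = np.add.reduceat(A[c2], ev_pos, axis=0)
            im = IndividualModel(ev_pos=ev_pos, r1=r1, r2=r2, fl=fl, E=E,
                                 g1=g1, g2a=g2a, g2b=g2b, v=v_full,
                                 eps=cfg.epsilon)
            M, _ = forward_summation(im)
            q1, q2, d, i1, i2 = backward_pass(im, M, rng, cfg.mode)
            if allow_super:
                q1 = _materialize_super(q1, i1, P - 1, residual)
                q2 = _materialize_super(q2, i2, P - 1, residual)
            # write back at SNP resolution
            xi[ev_pos] -= I[c1, ev_pos].astype(np.int64)
            xi[ev_pos] -= I[c2, ev_pos].astype(np.int64)
            bounds = np.append(ev_pos, L)
            for t in range(T):
                Q[c1, bounds[t]:bounds[t + 1]] = q1[t]
                Q[c2, bounds[t]:bounds[t + 1]] = q2[t]
            I[c1] = False
            I[c2] = False
            I[c1, ev_pos[1:]] = i1[1:].astype(bool)
            I[c2, ev_pos[1:]] = i2[1:].astype(bool)
            xi[ev_pos] += i1 + i2
            if allow_super:
                q_star = max(q_star, residual.max_issued + 1)
        if trace is not None:
            trace(sweep, Q, I)
        if sweep >= cfg.n_burnin:
            Qc = np.minimum(Q, max_pops - 1)
            np.add.at(acc_labels, (np.arange(n_chains)[:, None], cols[None, :], Qc), 1)
            occ = np.zeros((L, max_pops), dtype=bool)
            occ[cols[None, :], Qc] = True
            acc_npop[cols, occ.sum(axis=1)] += 1
            acc_rate += I.sum(axis=0) / n_chains
            n_acc += 1

    freq = acc_labels.astype(np.float64) / n_acc
    map_labels = np.argmax(acc_labels, axis=2)
    if denovo:
        # stick labels are arbitrary: relabel densely by first appearance.
        # Fixed-K labels are meaningful (pinned references), so keep them.
        map_labels, freq = _relabel_by_appearance(map_labels, freq)
    return PosteriorSummary(map_labels=map_labels, label_freq=freq,
                            n_pops_map=np.argmax(acc_npop, axis=1),
                            admix_rate=acc_rate / n_acc, n_sweeps=n_acc)


def _materialize_super(q: np.ndarray, i_ev: np.ndarray, super_idx: int,
                       residual: ResidualStick) -> np.ndarray:
    """Convert super-state selections into concrete new labels.

    A fresh label is drawn at the chain start and at every admixture event
    that lands on the super state; between events the label is copied.
    """
    q = q.copy()
    label = -1
    for t in range(q.size):
        if q[t] == super_idx:
            if t == 0 or i_ev[t] == 1 or label < 0:
                label = residual.sample()
            q[t] = label
        else:
            label = -1
    return q


def _relabel_by_appearance(map_labels: np.ndarray, freq: np.ndarray):
    """Dense relabeling 0..K-1 by first appearance along the genome."""
    order = []
    seen = set()
    for j in range(map_labels.shape[1]):
        for lab in map_labels[:, j]:
            if lab not in seen:
                seen.add(lab)
                order.append(int(lab))
    mapping = np.arange(freq.shape[2])
    for new, old in enumerate(order):
        mapping[old] = new
    # unseen labels keep distinct indices after the seen ones
    nxt = len(order)
    for old in range(freq.shape[2]):
        if old not in seen:
            mapping[old] = nxt
            nxt += 1
    new_labels = mapping[map_labels]
    new_freq = np.empty_like(freq)
    new_freq[:, :, mapping] = freq
    return new_labels, new_freq


def sample_new_label(residual: ResidualStick) -> int:
    """Draw a fresh population label from the residual stick (re-export)."""
    return residual.sample()
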