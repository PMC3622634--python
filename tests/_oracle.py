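"""Brute-force enumeration oracle for the per-individual conditional.

Independent re-implementation of the target distribution over
(Q_i, I_i, delta_i) at event resolution, by explicit depth-first
enumeration of every configuration. Used to check forward marginals,
log-likelihoods, MAP paths and backward-sampling frequencies produced by
the production kernels. Deliberately written as plain recursive Python
over explicit probability factors -- no message passing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class OracleResult:
    filtering: list          # per event t: dict {(q1,q2,d): prob}, normalized
    log_z: float             # total data log-likelihood
    map_path: list           # [(q1, q2, d, i1, i2)] per event, best config
    map_logprob: float
    posterior: dict          # full path -> posterior probability


def _pair_case_probs(free1, free2, g1, g2a, g2b):
    """Joint probability of (I1, I2) under the sequential pair predictive."""
    p1 = g1 if free1 else 0.0
    out = {}
    for i1 in ((0, 1) if free1 else (0,)):
        pi1 = p1 if i1 else 1.0 - p1
        g2 = (g2b if i1 else g2a) if free2 else 0.0
        for i2 in ((0, 1) if free2 else (0,)):
            pi2 = g2 if i2 else 1.0 - g2
            out[(i1, i2)] = pi1 * pi2
    return out


def enumerate_individual(r1, r2, fl, E, g1, g2a, g2b, v, eps) -> OracleResult:
    """Enumerate all (Q, I, delta) configurations of one individual.

    Arguments mirror the production kernel's inputs: per-event flags for
    chain-1 redraws, chain-2 redraws and switch flips; interval emission
    log-sums E[t, l, q]; sequential predictives; population weights v
    (super-state mass last when present); switch-error probability eps.
    """
    T = E.shape[0]
    P = len(v)
    filtering = [dict() for _ in range(T)]
    leaves = {}
    best = (-math.inf, None)

    def emis(t, q1, q2, d):
        if d == 0:
            return E[t, 0, q1] + E[t, 1, q2]
        return E[t, 1, q1] + E[t, 0, q2]

    def visit(t, q1, q2, d, logw, path):
        key = (q1, q2, d)
        filtering[t][key] = filtering[t].get(key, 0.0) + math.exp(logw)
        if t == T - 1:
            nonlocal best
            leaves[tuple(path)] = leaves.get(tuple(path), 0.0) + math.exp(logw)
            if logw > best[0]:
                best = (logw, list(path))
            return
        cases = _pair_case_probs(bool(r1[t + 1]), bool(r2[t + 1]),
                                 g1[t + 1], g2a[t + 1], g2b[t + 1])
        for (i1, i2), pc in cases.items():
            if pc <= 0.0:
                continue
            for nq1 in (range(P) if i1 else (q1,)):
                w1 = v[nq1] if i1 else 1.0
                if w1 <= 0.0:
                    continue
                for nq2 in (range(P) if i2 else (q2,)):
                    w2 = v[nq2] if i2 else 1.0
                    if w2 <= 0.0:
                        continue
                    for nd in ((0, 1) if fl[t + 1] else (d,)):
                        wd = ((1.0 - eps) if nd == d else eps) if fl[t + 1] else 1.0
                        step = pc * w1 * w2 * wd
                        visit(t + 1, nq1, nq2, nd,
                              logw + math.log(step) + emis(t + 1, nq1, nq2, nd),
                              path + [(nq1, nq2, nd, i1, i2)])

    for q1 in range(P):
        if v[q1] <= 0.0:
            continue
        for q2 in range(P):
            if v[q2] <= 0.0:
                continue
            for d in (0, 1):
                pd = (1.0 - eps) if d == 0 else eps
                logw = math.log(v[q1] * v[q2] * pd) + emis(0, q1, q2, d)
                visit(0, q1, q2, d, logw, [(q1, q2, d, 0, 0)])

    z = sum(leaves.values())
    for t in range(T):
        tot = sum(filtering[t].values())
        for k in filtering[t]:
            filtering[t][k] /= tot
    posterior = {k: w / z for k, w in leaves.items()}
    return OracleResult(filtering=filtering, log_z=math.log(z),
                        map_path=best[1], map_logprob=best[0],
                        posterior=posterior)


def random_toy(rng, max_events=4, max_pops=4):
    """A random small individual model (arrays for kernel and oracle)."""
    T = int(rng.integers(2, max_events + 1))
    P = int(rng.integers(2, max_pops + 1))
    if T >= 4:
        P = min(P, 3)  # keep the enumeration tractable
    r1 = np.zeros(T, dtype=bool)
    r2 = np.zeros(T, dtype=bool)
    fl = np.zeros(T, dtype=bool)
    for t in range(1, T):
        r1[t] = rng.random() < 0.7
        r2[t] = rng.random() < 0.7
        fl[t] = rng.random() < 0.5
        if not (r1[t] or r2[t] or fl[t]):
            r1[t] = True
    E = np.log(rng.uniform(0.05, 1.0, size=(T, 2, P)))
    g1 = rng.uniform(0.02, 0.7, size=T)
    g2a = rng.uniform(0.02, 0.7, size=T)
    g2b = rng.uniform(0.02, 0.7, size=T)
    v = rng.dirichlet(np.ones(P))
    eps = float(rng.choice([0.5, 0.3, 0.2]))
    return dict(r1=r1, r2=r2, fl=fl, E=E, g1=g1, g2a=g2a, g2b=g2b,
                v=v, eps=eps)
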