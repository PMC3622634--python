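"""Evaluation metrics: adjusted Rand index, per-SNP label mapping,
local-ancestry error, and per-SNP population counts.

The adjusted Rand index scores stratification (whole individuals assigned
to clusters); for admixed individuals -- who carry segments from several
origins -- accuracy is instead the percentage of incorrect local ancestry,
computed per SNP after mapping the inferred labels to true labels on
reference haplotypes, then averaged over SNPs. Diploid comparisons are
phase-agnostic: at each SNP the two inferred labels of an individual are
matched to the two true labels as an unordered pair, consistent with the
model's switch-error tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

UNMATCHED = -1


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index between two partitions of the same items.

    1 means identical partitions (up to label permutation), 0 the expected
    agreement of random labelings; valid when the two partitions have
    different numbers of clusters.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def map_labels_per_snp(inferred: np.ndarray, ref_truth: np.ndarray,
                       ref_chains: np.ndarray) -> np.ndarray:
    """Map inferred population labels to true labels, independently per SNP.

    ``inferred`` is (2N, L) over all haplotype chains (samples and
    references); ``ref_chains`` indexes the reference chains and
    ``ref_truth`` gives their true labels, either as a 1-D per-chain vector
    (constant ancestry) or a (n_ref_chains, L) matrix. At each SNP a
    one-to-one assignment between inferred and true labels maximizing the
    agreement on the reference chains is found; all chains are relabeled
    accordingly, and inferred labels without reference support map to -1
    ("unmatched").
    """
    inferred = np.asarray(inferred)
    ref_chains = np.asarray(ref_chains)
    if ref_chains.size == 0:
        raise ValueError("label mapping requires reference haplotypes")
    ref_truth = np.asarray(ref_truth)
    if ref_truth.ndim == 1:
        ref_truth = np.broadcast_to(ref_truth[:, None],
                                    (ref_truth.size, inferred.shape[1]))
    L = inferred.shape[1]
    out = np.empty_like(inferred)
    for j in range(L):
        inf_j = inferred[:, j]
        ref_inf = inf_j[ref_chains]
        ref_tru = ref_truth[:, j]
        inf_labels = np.unique(inf_j)
        tru_labels = np.unique(ref_tru)
        agree = np.zeros((inf_labels.size, tru_labels.size))
        for a, la in enumerate(inf_labels):
            sel = ref_inf == la
            for b, lb in enumerate(tru_labels):
                agree[a, b] = np.count_nonzero(sel & (ref_tru == lb))
        rows, colsel = linear_sum_assignment(-agree)
        mapping = {int(la): UNMATCHED for la in inf_labels}
        for a, b in zip(rows, colsel):
            mapping[int(inf_labels[a])] = int(tru_labels[b])
        out[:, j] = [mapping[int(x)] for x in inf_j]
    return out


def local_ancestry_error(inferred: np.ndarray,
                         truth: np.ndarray) -> tuple[float, float]:
    """Mean percentage of incorrect local ancestry, with its standard error.

    Computed at each SNP separately and then averaged over SNPs. At each
    SNP each individual's two labels are compared to the two true labels as
    unordered pairs (best pairing), so strand swaps are not penalized.
    Returns (fraction, standard error over SNPs).
    """
    inferred = np.asarray(inferred)
    truth = np.asarray(truth)
    if inferred.shape != truth.shape:
        raise ValueError("inferred and truth shapes must match")
    n_chains, L = inferred.shape
    i1, i2 = inferred[0::2], inferred[1::2]
    t1, t2 = truth[0::2], truth[1::2]
    direct = (i1 != t1).astype(np.int64) + (i2 != t2).astype(np.int64)
    crossed = (i1 != t2).astype(np.int64) + (i2 != t1).astype(np.int64)
    mism = np.minimum(direct, crossed)          # (N, L) in {0, 1, 2}
    per_snp = mism.sum(axis=0) / n_chains
    err = float(per_snp.mean())
    se = float(per_snp.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0
    return err, se


def populations_per_snp(Q) -> np.ndarray:
    """Number of distinct population labels at each SNP.

    ``Q`` is a single (2N, L) label matrix, or a sequence of posterior
    sample matrices, in which case the per-SNP MAP count over samples is
    returned.
    """
    if isinstance(Q, np.ndarray) and Q.ndim == 2:
        samples = [Q]
    else:
        samples = list(Q)
    L = samples[0].shape[1]
    counts = np.zeros((L, samples[0].shape[0] + 1), dtype=np.int64)
    for mat in samples:
        for j in range(L):
            counts[j, np.unique(mat[:, j]).size] += 1
    return np.argmax(counts, axis=1)


def stratification_partition(summary_labels: np.ndarray) -> np.ndarray:
    """Per-individual cluster assignment from per-SNP haplotype labels.

    For stratified samples each individual has a single origin; the
    assignment is the individual's modal label over both haplotypes and all
    SNPs.
    """
    labels = np.asarray(summary_labels)
    n_ind = labels.shape[0] // 2
    out = np.empty(n_ind, dtype=np.int64)
    for i in range(n_ind):
        vals, counts = np.unique(labels[2 * i:2 * i + 2], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out
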