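"""Genetic maps and per-SNP crossover probabilities.

A genetic map anchors physical coordinates (bp) to cumulative genetic
distance in centimorgan (1 cM = 1% crossover probability per generation).
The quantity consumed by both the simulator and the admixture prior is
``d_j``, the per-generation crossover probability between SNPs j-1 and j,
obtained by linear interpolation of the cumulative map at the SNP positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative genetic map: physical anchors (bp) -> position in cM.

    Parameters
    ----------
    positions
        Strictly increasing physical coordinates of the map anchors, in bp.
    cm
        Cumulative genetic position at each anchor, in centimorgan;
        non-decreasing.
    """

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if pos.ndim != 1 or pos.shape != cm.shape:
            raise ValueError("positions and cm must be 1-D arrays of equal length")
        if pos.size < 2:
            raise ValueError("a genetic map needs at least two anchors")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("map positions must be strictly increasing")
        if not np.all(np.diff(cm) >= 0):
            raise ValueError("cumulative cM must be non-decreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cm", cm)

    def cm_at(self, snp_positions) -> np.ndarray:
        """Cumulative cM at arbitrary positions (linear interpolation).

        Positions beyond the anchored range are extrapolated with the
        recombination rate of the nearest map interval.
        """
        q = np.asarray(snp_positions, dtype=float)
        if q.ndim != 1:
            raise ValueError("snp_positions must be 1-D")
        if q.size > 1 and not np.all(np.diff(q) >= 0):
            raise ValueError("snp_positions must be sorted")
        out = np.interp(q, self.positions, self.cm)
        # linear extrapolation with edge interval rates
        lo_rate = (self.cm[1] - self.cm[0]) / (self.positions[1] - self.positions[0])
        hi_rate = (self.cm[-1] - self.cm[-2]) / (self.positions[-1] - self.positions[-2])
        below = q < self.positions[0]
        above = q > self.positions[-1]
        out[below] = self.cm[0] + (q[below] - self.positions[0]) * lo_rate
        out[above] = self.cm[-1] + (q[above] - self.positions[-1]) * hi_rate
        return out

    def interpolate(self, snp_positions) -> np.ndarray:
        """Per-SNP crossover probabilities d_j between SNPs j-1 and j.

        Returns an array of the same length as ``snp_positions`` whose first
        entry is 0 (a Markov chain start has no incoming interval); entry j
        is (cM_j - cM_{j-1}) / 100, clipped at 0.
        """
        cm = self.cm_at(snp_positions)
        d = np.zeros_like(cm)
        d[1:] = np.maximum(np.diff(cm), 0.0) / 100.0
        return d


def uniform_map(length_bp: float, cm_per_mb: float = 1.0) -> GeneticMap:
    """Constant-rate map over [0, length_bp] (default 1 cM/Mb)."""
    return GeneticMap(
        positions=np.array([0.0, float(length_bp)]),
        cm=np.array([0.0, float(length_bp) / 1e6 * cm_per_mb]),
    )


def interpolate_map(gmap: GeneticMap, snp_positions) -> np.ndarray:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(snp_positions)


def admix_probability(lam: float, d_j) -> np.ndarray:
    """Probability 1 - exp(-lam * d_j) of an admixture event at each SNP.

    ``lam`` is the number of generations since admixture; ``lam = 0``
    recovers pure stratification (no events anywhere).
    """
    d = np.asarray(d_j, dtype=float)
    if lam < 0:
        raise ValueError("lambda (generations) must be >= 0")
    if np.any(d < 0):
        raise ValueError("d_j must be >= 0")
    return -np.expm1(-lam * d)
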