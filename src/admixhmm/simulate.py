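"""Synthetic admixed samples: ancestral panels, mosaic haplotypes, reads.

The generator emulates the study conditions used throughout the package's
benchmarks: K ancestral populations with divergent allele frequencies
(a Balding-Nichols-style model with fixation index F), admixed diploid
individuals built as mosaics of ancestral template haplotypes, per-SNP
across-population admixture probability 1 - exp(-lambda * d_j) under a
genetic map, within-population template recombination at an expected rate
of 1 per 200 kb, and Poisson-distributed sequencing reads at a chosen mean
coverage. Ground-truth ancestry is recorded per haplotype per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, admix_probability, uniform_map

DEFAULT_WITHIN_POP_RECOMB = 1.0 / 200_000.0  # recombinations per bp
DEFAULT_COVERAGE = 8.0


@dataclass
class AncestralPanel:
    """K ancestral populations: allele frequencies and template haplotypes.

    ``freqs`` has shape (K, L) with the minor-allele frequency of each
    population at each SNP. ``haplotypes`` is an optional per-population pool
    of phased template haplotypes, each of shape (n_templates, L) in {0,1};
    when present, simulated individuals copy alleles from templates (which
    creates realistic linkage disequilibrium), otherwise alleles are drawn
    independently from ``freqs``.
    """

    freqs: np.ndarray
    positions: np.ndarray
    haplotypes: list[np.ndarray] | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be (K, L)")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.positions.shape != (self.freqs.shape[1],):
            raise ValueError("positions must have length L")
        if self.haplotypes is not None:
            if len(self.haplotypes) != self.n_pops:
                raise ValueError("one haplotype pool per population required")
            for pool in self.haplotypes:
                if pool.shape[0] < 2:
                    raise ValueError("each population pool needs >= 2 haplotypes")
                if pool.shape[1] != self.n_snps:
                    raise ValueError("pool width must equal L")

    @property
    def n_pops(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]


@dataclass
class AdmixtureConfig:
    """Admixture scenario: generations, proportions, recombination, coverage.

    ``lam`` is the number of generations since the admixture event;
    ``proportions`` are the per-population contributions (sum to 1);
    ``within_pop_recomb_rate`` is the per-bp rate at which a haplotype
    switches template within its current population (default 1 / 200 kb);
    ``coverage`` the mean sequencing depth for the read simulator.
    """

    lam: float
    proportions: np.ndarray
    within_pop_recomb_rate: float = DEFAULT_WITHIN_POP_RECOMB
    coverage: float = DEFAULT_COVERAGE

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("admixture proportions must sum to 1")
        if np.any(self.proportions < 0):
            raise ValueError("admixture proportions must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class TruthTrack:
    """Ground-truth ancestry: per-haplotype per-SNP population labels.

    ``labels`` has shape (2N, L); chain 2*i + l is haplotype l (0 or 1) of
    individual i. Labels are 0-based population indices (serialized 1-based).
    """

    labels: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_chains(self) -> int:
        return self.labels.shape[0]

    @property
    def n_snps(self) -> int:
        return self.labels.shape[1]

    def populations_per_snp(self) -> np.ndarray:
        """True number of distinct populations present at each SNP."""
        L = self.n_snps
        out = np.empty(L, dtype=int)
        for j in range(L):
            out[j] = np.unique(self.labels[:, j]).size
        return out

    def switch_count(self) -> np.ndarray:
        """Number of visible ancestry switches along each haplotype."""
        return (np.diff(self.labels, axis=1) != 0).sum(axis=1)


def generate_panel(
    n_pops: int,
    n_snps: int,
    *,
    fixation: float = 0.2,
    n_templates: int = 20,
    spacing_bp: float = 10_000.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> AncestralPanel:
    """Draw divergent ancestral populations from a Balding-Nichols model.

    An ancestral frequency p ~ Uniform(0.05, 0.95) is drawn per SNP; each
    population's frequency is then Beta(p(1-F)/F, (1-p)(1-F)/F) with
    fixation index F (default 0.2), which produces the separated allele
    frequency spectra of long-diverged populations. A pool of
    ``n_templates`` template haplotypes is sampled per population.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_pops < 1:
        raise ValueError("need at least one population")
    if not 0 < fixation < 1:
        raise ValueError("fixation index must lie in (0, 1)")
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    scale = (1.0 - fixation) / fixation
    freqs = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(n_pops, n_snps))
    freqs = np.clip(freqs, 1e-4, 1.0 - 1e-4)
    pools = [
        (rng.random((n_templates, n_snps)) < freqs[k]).astype(np.int8)
        for k in range(n_pops)
    ]
    positions = np.arange(n_snps, dtype=float) * spacing_bp
    return AncestralPanel(freqs=freqs, positions=positions, haplotypes=pools)


def simulate_admixed_sample(
    panel: AncestralPanel,
    cfg: AdmixtureConfig,
    gmap: GeneticMap | None,
    n_individuals: int,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, TruthTrack]:
    """Simulate mosaic admixed haplotypes with a ground-truth ancestry track.

    Each individual draws a founding population from the admixture
    proportions, shared by its two haplotypes (so that lam = 0 yields
    cleanly stratified individuals); along the genome each haplotype then
    admixes independently: at every SNP j >= 1 an admixture event occurs
    with probability 1 - exp(-lam * d_j) and redraws the population from
    the proportions (the redraw may land on the same population, so
    visible switches are a subset of events). Within the current population
    the template haplotype recombines with per-interval probability
    min(1, rate * bp gap). Alleles are copied from the template pool, or
    drawn Bernoulli(freq) for a frequency-only panel.

    Returns the (2N, L) haplotype matrix and the TruthTrack.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if panel.n_pops != cfg.proportions.size:
        raise ValueError("panel and config disagree on the number of populations")
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    L = panel.n_snps
    pos = panel.positions
    if gmap is None:
        gmap = uniform_map(pos[-1] + (pos[1] - pos[0] if L > 1 else 1.0))
    d = gmap.interpolate(pos)
    p_admix = admix_probability(cfg.lam, d)
    gaps = np.diff(pos, prepend=pos[0])
    p_recomb = np.minimum(1.0, cfg.within_pop_recomb_rate * gaps)
    p_recomb[0] = 0.0

    n_chains = 2 * n_individuals
    H = np.zeros((n_chains, L), dtype=np.int8)
    labels = np.zeros((n_chains, L), dtype=np.int32)
    pools = panel.haplotypes

    founding = rng.choice(panel.n_pops, p=cfg.proportions, size=n_individuals)
    for c in range(n_chains):
        pop = int(founding[c // 2])
        tmpl = rng.integers(pools[pop].shape[0]) if pools is not None else -1
        admix_draws = rng.random(L)
        recomb_draws = rng.random(L)
        for j in range(L):
            if j > 0:
                if admix_draws[j] < p_admix[j]:
                    pop = rng.choice(panel.n_pops, p=cfg.proportions)
                    if pools is not None:
                        tmpl = rng.integers(pools[pop].shape[0])
                elif recomb_draws[j] < p_recomb[j]:
                    if pools is not None:
                        tmpl = rng.integers(pools[pop].shape[0])
            labels[c, j] = pop
            if pools is not None:
                H[c, j] = pools[pop][tmpl, j]
            else:
                H[c, j] = rng.random() < panel.freqs[pop, j]
    return H, TruthTrack(labels=labels, positions=pos.copy())


def simulate_reads(
    genotypes: np.ndarray,
    coverage: float = DEFAULT_COVERAGE,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Poisson sequencing reads from a dosage matrix.

    For each individual and SNP with minor-allele dosage g in {0,1,2}, the
    minor-allele read count is Poisson(coverage * g / 2) and the
    major-allele count Poisson(coverage * (2 - g) / 2), so the total depth
    has mean ``coverage``. Returns an (N, L, 2) array ordered
    (major, minor) -- i.e. (ref, alt) counts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    g = np.asarray(genotypes)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("dosages must lie in {0, 1, 2}")
    minor = rng.poisson(coverage * g / 2.0)
    major = rng.poisson(coverage * (2.0 - g) / 2.0)
    return np.stack([major, minor], axis=-1)


def filter_nonpolymorphic(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop SNPs at which every called allele is identical.

    Mirrors the post-genotyping cleanup step applied to reconstructed data
    before inference. Returns the reduced matrix and the array of kept
    original column indices.
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise ValueError("calls must be a 2-D matrix (rows x SNPs)")
    keep = np.ptp(calls, axis=0) > 0
    kept_idx = np.flatnonzero(keep)
    return calls[:, keep], kept_idx
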