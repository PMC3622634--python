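"""Reusable benchmark harness: simulate, segment, infer, score.

Bundles the evaluation protocol used throughout the package's examples and
tests: simulate an admixed sample plus pure reference individuals from one
ancestral panel, run the segmentation and admixture layers in one of three
information regimes, map inferred labels to the truth on the reference
haplotypes, and report the percentage of incorrect local ancestry on the
admixed individuals.

Regimes ("modes"):

* ``"2ref"``  -- reference individuals with known labels are given to the
  model (fixed number of populations C, references pinned);
* ``"0ref"``  -- the number of populations is given but no labels; the
  references are present as ordinary unlabeled individuals;
* ``"denovo"`` -- neither labels nor the number of populations.

In all three regimes the references take part in the fit, and scoring maps
inferred labels to true labels at each SNP via the reference haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import FitConfig, fit
from .hapseg import HapsegConfig, infer_haplotype_structure
from .metrics import local_ancestry_error, map_labels_per_snp
from .simulate import AdmixtureConfig, TruthTrack, generate_panel, \
    simulate_admixed_sample

# the benchmark keeps the SNP density of dense human sequencing panels
# (~1 SNP per 750 bp, ~1 cM/Mb) and scales the region length down with the
# SNP count, so ancestry-block lengths in SNP units match the full-scale
# setting
DEFAULT_SPACING_BP = 750.0


@dataclass
class AdmixedDataset:
    """Admixed sample plus pure references drawn from one panel."""

    haplotypes: np.ndarray      # (2N_total, L): samples first, refs after
    truth: TruthTrack
    ref_labels: np.ndarray      # per individual; -1 for sample individuals
    positions: np.ndarray
    n_sample: int

    @property
    def sample_chains(self) -> np.ndarray:
        return np.arange(2 * self.n_sample)

    @property
    def ref_chains(self) -> np.ndarray:
        return np.arange(2 * self.n_sample, self.haplotypes.shape[0])


def make_admixed_dataset(n_pops: int, lam: float, n_sample: int,
                         n_ref_per_pop: int, n_snps: int, seed: int,
                         spacing_bp: float = DEFAULT_SPACING_BP,
                         fixation: float = 0.2) -> AdmixedDataset:
    """Simulate admixed individuals and pure references from one panel."""
    rng = np.random.default_rng(seed)
    panel = generate_panel(n_pops, n_snps, fixation=fixation,
                           spacing_bp=spacing_bp, rng=rng)
    props = np.full(n_pops, 1.0 / n_pops)
    H_s, truth_s = simulate_admixed_sample(
        panel, AdmixtureConfig(lam=lam, proportions=props), None,
        n_sample, rng=rng)
    blocks_H = [H_s]
    blocks_T = [truth_s.labels]
    ref_labels = [-1] * n_sample
    for k in range(n_pops):
        onehot = np.zeros(n_pops)
        onehot[k] = 1.0
        H_r, truth_r = simulate_admixed_sample(
            panel, AdmixtureConfig(lam=0.0, proportions=onehot), None,
            n_ref_per_pop, rng=rng)
        blocks_H.append(H_r)
        blocks_T.append(truth_r.labels)
        ref_labels += [k] * n_ref_per_pop
    H = np.vstack(blocks_H)
    truth = TruthTrack(labels=np.vstack(blocks_T), positions=panel.positions)
    return AdmixedDataset(haplotypes=H, truth=truth,
                          ref_labels=np.array(ref_labels, dtype=np.int64),
                          positions=panel.positions, n_sample=n_sample)


def run_mode(ds: AdmixedDataset, mode: str, seed: int,
             hapstruct=None, fit_kwargs: dict | None = None):
    """Fit one information regime and score local-ancestry error.

    Returns (error fraction on the admixed individuals, PosteriorSummary).
    The haplotype structure may be passed in so that the three regimes
    share one segmentation of the same data.
    """
    n_pops = int(ds.ref_labels.max()) + 1
    if hapstruct is None:
        hapstruct = infer_haplotype_structure(
            ds.haplotypes, HapsegConfig(seed=seed))
    kw = dict(fit_kwargs or {})
    if mode == "2ref":
        cfg = FitConfig(seed=seed, fixed_K=n_pops, **kw)
        summary = fit(hapstruct, ref_labels=ds.ref_labels, cfg=cfg)
    elif mode == "0ref":
        cfg = FitConfig(seed=seed, fixed_K=n_pops, **kw)
        summary = fit(hapstruct, cfg=cfg)
    elif mode == "denovo":
        cfg = FitConfig(seed=seed, **kw)
        summary = fit(hapstruct, cfg=cfg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    err = score_local_ancestry(ds, summary.map_labels)
    return err, summary


def score_local_ancestry(ds: AdmixedDataset, inferred: np.ndarray) -> float:
    """Percentage of incorrect local ancestry on the admixed individuals.

    Labels are mapped to the truth at each SNP on the reference haplotypes,
    then scored phase-agnostically on the sample haplotypes only.
    """
    ref_truth = ds.truth.labels[ds.ref_chains]
    mapped = map_labels_per_snp(inferred, ref_truth, ds.ref_chains)
    sc = ds.sample_chains
    err, _ = local_ancestry_error(mapped[sc], ds.truth.labels[sc])
    return err
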