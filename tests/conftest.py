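import numpy as np
import pytest

import admixhmm as ax


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_stratified():
    """Two well-separated populations, no admixture, with truth."""
    rng = np.random.default_rng(7)
    panel = ax.generate_panel(2, 600, fixation=0.2, rng=rng)
    cfg = ax.AdmixtureConfig(lam=0.0, proportions=[0.5, 0.5])
    H, truth = ax.simulate_admixed_sample(panel, cfg, None, 12, rng=rng)
    return panel, H, truth


@pytest.fixture(scope="session")
def toy_structure():
    """Hand-built haplotype structure with known segments.

    Individual 0: chain 0 changes state at SNP 4, chain 1 at SNPs 4 and 7
    (so SNP 4 is a double-recombination site). Individual 1: constant.
    """
    L = 10
    S = np.array([
        [0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
        [2, 2, 2, 2, 0, 0, 0, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [2, 2, 2, 2, 2, 2, 2, 2, 2, 2],
    ])
    phi = np.zeros((4, L), dtype=bool)
    phi[0, 4] = True
    phi[1, 4] = True
    phi[1, 7] = True
    r = np.full(L, 0.01)
    r[0] = 0.0
    return ax.HaplotypeStructure(states=S, transitions=phi, recomb_prob=r)
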