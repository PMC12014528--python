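import numpy as np
import pytest

import erosionkit as ek
from erosionkit import gl, simdata


@pytest.fixture(scope="session")
def small_cohort():
    """Bottlenecked two-epoch cohort at the default study conditions."""
    cfg = ek.SimConfig(seed=1)
    geno, truth = ek.simulate_genotypes(cfg)
    return cfg, geno, truth


@pytest.fixture(scope="session")
def dense_panel():
    """SNP-dense panel (high theta) suitable for ROH and structure analyses."""
    cfg = ek.SimConfig(
        theta=0.2, n_sites=20_000, n_scaffolds=2, scaffold_length=50_000_000,
        n_historic=5, n_contemporary=5, seed=3,
    )
    geno, truth = ek.simulate_genotypes(cfg)
    return cfg, geno, truth


def make_pileup_from_counts(counts, quality=30.0, positions=None, scaffold="scaf1"):
    """Pileup helper for hand-built base-count matrices."""
    counts = np.asarray(counts)
    n_sites = counts.shape[1]
    return gl.Pileup(
        scaffolds=np.array([scaffold] * n_sites, dtype=object),
        positions=np.asarray(positions)
        if positions is not None
        else np.arange(1, n_sites + 1),
        counts=counts,
        quality=quality,
    )
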