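import numpy as np
import pandas as pd
import pytest

from germid import simdata
from germid.variant_io import GenotypeMatrix


def make_matrix(dosages, chroms=None, positions=None, refs=None, alts=None,
                sample_ids=None, groups=None):
    """Hand-rolled GenotypeMatrix for small fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chroms = chroms or ["chr1"] * m
    positions = positions or list(range(1, m + 1))
    refs = refs or ["A"] * m
    alts = alts or ["G"] * m
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n)]
    groups = groups or ["g"] * n
    samples = pd.DataFrame({"accession_id": sample_ids, "group": groups})
    return GenotypeMatrix(dosages, loci, samples)


@pytest.fixture
def small_panel():
    """60-sample, 120-locus structured panel with light missingness."""
    cfg = simdata.SimConfig(n_samples=60, n_loci=120, n_pops=3,
                            divergence=0.15, admixed_fraction=0.2,
                            missing_rate=0.01, seed=11)
    matrix, truth = simdata.simulate_panel(cfg)
    return matrix, truth


@pytest.fixture
def clean_panel():
    """No-missing panel for exact round-trip checks."""
    cfg = simdata.SimConfig(n_samples=25, n_loci=60, n_pops=2,
                            divergence=0.1, admixed_fraction=0.2,
                            missing_rate=0.0, seed=5)
    matrix, _ = simdata.simulate_panel(cfg)
    return matrix
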