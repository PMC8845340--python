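import numpy as np
import pytest

import phaseval as pv


def make_hapset(hapA, hapB, phased=None, positions=None, chrom="1",
                sample_ids=None):
    """Build a single- or multi-sample HaplotypeSet from 1-D or 2-D arrays."""
    hapA = np.asarray(hapA, dtype=np.int8)
    hapB = np.asarray(hapB, dtype=np.int8)
    if hapA.ndim == 1:            # single sample: (n_var,) -> (n_var, 1)
        hapA, hapB = hapA[:, None], hapB[:, None]
    n_var, n_s = hapA.shape
    if positions is None:
        positions = np.arange(n_var) * 1000 + 1000
    if phased is None:
        phased = np.ones((n_var, n_s), dtype=bool)
    else:
        phased = np.asarray(phased, dtype=bool)
        if phased.ndim == 1:
            phased = phased[:, None]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_s)]
    return pv.HaplotypeSet(np.array([chrom] * n_var, dtype=object),
                           np.asarray(positions), sample_ids, hapA, hapB,
                           phased)


@pytest.fixture(scope="session")
def small_sim():
    """Clean two-chromosome pedigree simulation shared across tests."""
    cfg = pv.SimConfig(n_chrom=2, chrom_bp_length=10_000_000,
                       chrom_cM_length=100, n_variants_per_chrom=500,
                       n_founders=12, n_duos=6, n_trios=10, seed=11)
    return pv.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_gold(small_sim):
    return pv.phase_pedigree(small_sim.observed, small_sim.pedigree)
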