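"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's chained-orientation logic: the
switch-error oracle compares unordered two-locus haplotype pairs site by
site, and the QAN oracle scans candidate thresholds exhaustively.
"""

import numpy as np


def oracle_switch_errors(truth_hapA, truth_hapB, inf_hapA, inf_hapB,
                         inf_phased):
    """Count consecutive-pair discrepancies between inferred and true
    haplotypes over the inferred-phased sites (all sites are assumed
    informative: truth-het, truth-phased, concordant genotypes)."""
    idx = [k for k in range(len(truth_hapA)) if inf_phased[k]]
    sec = 0
    for a, b in zip(idx, idx[1:]):
        t = {(truth_hapA[a], truth_hapA[b]), (truth_hapB[a], truth_hapB[b])}
        i = {(inf_hapA[a], inf_hapA[b]), (inf_hapB[a], inf_hapB[b])}
        if t != i:
            sec += 1
    return sec


def oracle_qan50(blocks, total_snps):
    """Exhaustive threshold scan: the largest QA length L such that blocks
    with QA length >= L hold at least half of all informative SNPs."""
    candidates = sorted({b.qa_length for b in blocks}, reverse=True)
    for L in candidates:
        covered = sum(b.n_sites for b in blocks if b.qa_length >= L)
        if covered >= 0.5 * total_snps:
            return L
    return 0.0


def oracle_pairwise(positions, orientation, lo, hi):
    """Exhaustive pair enumeration: fraction of site pairs with separation
    in [lo, hi] whose orientations agree."""
    n = len(positions)
    total = correct = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[j] - positions[i]
            if lo <= d <= hi:
                total += 1
                correct += orientation[i] == orientation[j]
    return total, correct


def random_phasing_instance(rng, n_sites, unphase_prob=0.2):
    """A random truth/inferred pair over het sites: truth phased ordering,
    inferred with random orientation per site and random unphased sites.
    Returns (tA, tB, iA, iB, phased)."""
    tA = rng.integers(0, 2, n_sites).astype(np.int8)
    tB = (1 - tA).astype(np.int8)
    flip = rng.random(n_sites) < 0.5
    iA = np.where(flip, tB, tA).astype(np.int8)
    iB = np.where(flip, tA, tB).astype(np.int8)
    phased = rng.random(n_sites) > unphase_prob
    return tA, tB, iA, iB, phased
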