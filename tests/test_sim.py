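"""Simulator contracts: determinism, Mendelian transmission, Poisson
crossovers, noise calibration, and corruption/injection logging."""

import numpy as np
import pytest

import phaseval as pv
from phaseval.model import MISSING
from phaseval.sim import build_marker_map


def tiny_cfg(**kw):
    base = dict(n_chrom=1, chrom_bp_length=5_000_000, chrom_cM_length=50,
                n_variants_per_chrom=200, n_founders=8, n_duos=4, n_trios=6,
                seed=5)
    base.update(kw)
    return pv.SimConfig(**base)


class TestFounders:
    def test_fixed_frequency_gives_monomorphic(self):
        cfg = tiny_cfg(freq_range=(1.0, 1.0))
        hs, freqs = pv.simulate_founder_haplotypes(cfg, 5)
        assert (hs.hapA == 1).all() and (hs.hapB == 1).all()

    def test_empirical_frequency_matches_model(self):
        """ld_copy_prob=0, fixed freq 0.3: empirical frequency within
        3 binomial SE over 1e4 sites x 20 haplotypes."""
        cfg = tiny_cfg(n_variants_per_chrom=10_000, freq_range=(0.3, 0.3))
        hs, _ = pv.simulate_founder_haplotypes(cfg, 10)
        n = hs.hapA.size + hs.hapB.size
        se = np.sqrt(0.3 * 0.7 / n)
        emp = (hs.hapA.mean() + hs.hapB.mean()) / 2
        assert abs(emp - 0.3) < 3 * se

    def test_ld_copy_increases_adjacent_concordance(self):
        cfg0 = tiny_cfg(freq_range=(0.5, 0.5))
        cfg1 = tiny_cfg(freq_range=(0.5, 0.5), ld_copy_prob=0.9)
        h0, _ = pv.simulate_founder_haplotypes(cfg0, 20)
        h1, _ = pv.simulate_founder_haplotypes(cfg1, 20)
        c0 = (h0.hapA[1:] == h0.hapA[:-1]).mean()
        c1 = (h1.hapA[1:] == h1.hapA[:-1]).mean()
        assert c1 > c0 + 0.2

    def test_seed_determinism(self):
        a = pv.simulate_dataset(tiny_cfg())
        b = pv.simulate_dataset(tiny_cfg())
        assert np.array_equal(a.truth_haps.hapA, b.truth_haps.hapA)
        assert np.array_equal(a.observed.calls, b.observed.calls)
        for k in a.co_log:
            for c in a.co_log[k]:
                assert np.array_equal(a.co_log[k][c], b.co_log[k][c])


class TestGamete:
    def test_zero_cM_chromosome_never_recombines(self):
        rng = np.random.default_rng(0)
        pos = np.arange(100) * 1000
        cm = np.zeros(100)
        for _ in range(20):
            _, co = pv.simulate_gamete(np.zeros(100, dtype=np.int8),
                                       np.ones(100, dtype=np.int8),
                                       pos, cm, 1.0, rng)
            assert len(co) == 0

    def test_poisson_mean_one_on_100cM(self):
        rng = np.random.default_rng(1)
        pos = np.arange(100) * 1000
        cm = np.linspace(0, 100, 100)
        a = np.zeros(100, dtype=np.int8)
        b = np.ones(100, dtype=np.int8)
        n = 10_000
        counts = [len(pv.simulate_gamete(a, b, pos, cm, 1.0, rng)[1])
                  for _ in range(n)]
        se = np.sqrt(1.0 / n)
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_gamete_is_mosaic_with_breaks_at_crossovers(self):
        """Gamete equals one haplotype before each crossover and the other
        after, for distinguishable parental haplotypes."""
        rng = np.random.default_rng(2)
        pos = np.arange(500) * 10_000
        cm = np.linspace(0, 100, 500)
        a = np.zeros(500, dtype=np.int8)
        b = np.ones(500, dtype=np.int8)
        g, co = pv.simulate_gamete(a, b, pos, cm, 1.0, rng)
        source = np.searchsorted(co, pos, side="left") % 2
        expected = np.where(source == source[0], g[0], 1 - g[0])
        assert np.array_equal(g, expected)


class TestDataset:
    def test_clean_observed_equals_truth(self, small_sim):
        truth_gt = small_sim.truth_haps.genotypes()
        assert np.array_equal(small_sim.observed.calls, truth_gt.calls)

    def test_default_pedigree_counts(self):
        """Default configuration states the study-like pedigree: 264
        individuals, 98 trios, 279 parent-offspring pairs."""
        cfg = pv.SimConfig(n_chrom=1, n_variants_per_chrom=10, seed=0)
        sim = pv.simulate_dataset(cfg)
        ids = sim.observed.sample_ids
        assert len(ids) == 264
        assert len(sim.pedigree.find_trios(ids)) == 98
        assert len(sim.pedigree.parent_offspring_pairs(ids)) == 279

    def test_error_rate_calibration(self):
        cfg = tiny_cfg(n_variants_per_chrom=2000, genotype_error_rate=0.01)
        sim = pv.simulate_dataset(cfg)
        truth = sim.truth_haps.genotypes().calls
        n = truth.size
        disc = (sim.observed.calls != truth).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(disc - 0.01) < 3 * se

    def test_missing_rate_calibration(self):
        cfg = tiny_cfg(n_variants_per_chrom=2000, missing_rate=0.05)
        sim = pv.simulate_dataset(cfg)
        miss = (sim.observed.calls == MISSING).mean()
        se = np.sqrt(0.05 * 0.95 / sim.observed.calls.size)
        assert abs(miss - 0.05) < 3 * se

    def test_mendelian_consistency_when_clean(self, small_sim):
        assert pv.find_mendelian_inconsistencies(
            small_sim.observed, small_sim.pedigree) == []

    def test_transmission_mosaic_matches_co_log(self, small_sim):
        """Every offspring haplotype is the correct parent's mosaic with
        breakpoints exactly at the logged crossover positions."""
        sim = small_sim
        th = sim.truth_haps
        for (parent, child), per_chrom in list(sim.co_log.items())[:6]:
            jp, jc = th.sample_index(parent), th.sample_index(child)
            sire, _ = sim.pedigree.parents_of(child)
            child_hap = th.hapA if parent == sire else th.hapB
            for chrom, co in per_chrom.items():
                sl = th.chrom_slice(chrom)
                pos = th.positions[sl]
                g = child_hap[sl, jc]
                src = np.searchsorted(co, pos, side="left") % 2
                ok0 = np.where(src == 0, th.hapA[sl, jp], th.hapB[sl, jp])
                ok1 = np.where(src == 0, th.hapB[sl, jp], th.hapA[sl, jp])
                assert np.array_equal(g, ok0) or np.array_equal(g, ok1)


class TestCorruption:
    def test_zero_rates_identity(self, small_sim):
        out, log = pv.corrupt_haplotypes(small_sim.truth_haps, 0, 0, 0, seed=1)
        assert np.array_equal(out.hapA, small_sim.truth_haps.hapA)
        assert np.array_equal(out.phased, small_sim.truth_haps.phased)
        assert len(log) == 0

    def test_long_switch_poisson_count(self):
        """100 chromosomes x ~100 Mb at 0.05 switches/Mb: logged long
        switches within 3 SE of 500."""
        n_chrom, n_sites = 100, 20
        chroms = np.repeat([f"c{i:03d}" for i in range(n_chrom)], n_sites)
        pos = np.tile(np.linspace(0, 100e6, n_sites).astype(np.int64), n_chrom)
        shape = (n_chrom * n_sites, 1)
        hs = pv.HaplotypeSet(chroms.astype(object), pos, ["S"],
                             np.zeros(shape, np.int8), np.ones(shape, np.int8),
                             np.ones(shape, bool))
        _, log = pv.corrupt_haplotypes(hs, long_switch_rate_per_Mb=0.05,
                                       seed=3)
        n_long = (log["kind"] == "long_switch").sum()
        assert abs(n_long - 500) < 3 * np.sqrt(500)

    def test_unphase_fraction(self, small_sim):
        out, log = pv.corrupt_haplotypes(small_sim.truth_haps,
                                         unphase_fraction=0.25, seed=4)
        het = small_sim.truth_haps.hapA != small_sim.truth_haps.hapB
        frac = 1 - out.phased[het].mean()
        assert abs(frac - 0.25) < 0.01
        assert (log["kind"] == "unphase").sum() == (~out.phased).sum()

    def test_genotypes_preserved(self, small_sim):
        out, _ = pv.corrupt_haplotypes(small_sim.truth_haps, 0.5, 0.01, 0.1,
                                       seed=5)
        assert np.array_equal(out.genotypes().calls,
                              small_sim.truth_haps.genotypes().calls)

    def test_negative_rate_rejected(self, small_sim):
        with pytest.raises(ValueError):
            pv.corrupt_haplotypes(small_sim.truth_haps, -0.1)


class TestInjection:
    def test_zero_artifacts_identity(self, small_sim):
        assert pv.inject_artifact_variants(small_sim, 0) is small_sim

    def test_artifacts_flagged_and_sorted(self, small_sim):
        out = pv.inject_artifact_variants(small_sim, 50, "iid_hwe", seed=6)
        assert out.artifact_flags.sum() == 50
        assert out.observed.n_variants == small_sim.observed.n_variants + 50
        for _, sl in out.observed.iter_chromosomes():
            assert (np.diff(out.observed.positions[sl]) > 0).all()

    def test_excess_het_mode_violates_hwe(self):
        """With enough individuals, an all-carriers-heterozygous artifact
        fails the Hardy-Weinberg test."""
        from phaseval.qc_variants import hwe_test_many
        sim = pv.simulate_dataset(tiny_cfg(n_variants_per_chrom=10,
                                           n_founders=150, n_duos=0,
                                           n_trios=10))
        out = pv.inject_artifact_variants(sim, 30, "excess_het", seed=7,
                                          freq=0.5)
        calls = out.observed.calls[out.artifact_flags]
        assert (calls != 2).all()     # carriers are all heterozygous
        counts = np.stack([(calls == g).sum(axis=1) for g in (0, 1, 2)], axis=1)
        _, p = hwe_test_many(counts)
        assert np.median(p) < 0.05

    def test_map_error_zero_offset_identity(self, small_sim):
        assert pv.inject_map_errors(small_sim, 200_000, 0) is small_sim

    def test_map_error_recorded_and_consistent(self, small_sim):
        out = pv.inject_map_errors(small_sim, 200_000, 3_000_000, seed=8,
                                   chrom="1", block_start_bp=1_000_000)
        rec = out.relocations[0]
        assert rec["orig_start"] == 1_000_000 and rec["new_start"] == 4_000_000
        # genotype data travels with its markers: the same multiset of
        # (position-sorted) rows, permuted
        assert np.array_equal(np.sort(out.observed.calls.sum(axis=1)),
                              np.sort(small_sim.observed.calls.sum(axis=1)))
        for _, sl in out.observed.iter_chromosomes():
            assert (np.diff(out.observed.positions[sl]) > 0).all()
        assert (np.diff(out.marker_map.cM[out.marker_map.chroms == "1"])
                >= 0).all()
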