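"""Switch-error, block, QAN and pairwise-accuracy metrics, checked against
brute-force oracles and the simulator's corruption log."""

import numpy as np
import pytest

import phaseval as pv
from conftest import make_hapset
from oracles import (oracle_pairwise, oracle_qan50, oracle_switch_errors,
                     random_phasing_instance)
from phaseval.metrics import (build_blocks, count_switch_errors,
                              genome_fraction_in_blocks, informative_sites,
                              pairwise_accuracy, phasing_yield, qan50,
                              qan_curve)


def _pair(tA=None, n=None, positions=None):
    """Truth hapset of het sites (hapA alternating unless given)."""
    if tA is None:
        tA = np.tile([0, 1], n // 2 + 1)[:n].astype(np.int8)
    tA = np.asarray(tA, dtype=np.int8)
    tB = (1 - tA).astype(np.int8)
    return make_hapset(tA, tB, positions=positions)


def _profile(truth, inferred):
    return count_switch_errors(truth, inferred, "S0", "1")


class TestInformativeSites:
    def test_all_het_concordant(self):
        truth = _pair(n=10)
        info = informative_sites(truth, truth, "S0", "1")
        assert len(info.indices) == 10
        assert info.n_discordant == 0

    def test_truth_unphased_excluded(self):
        truth = _pair(n=10)
        truth.phased[3, 0] = False
        info = informative_sites(truth, truth, "S0", "1")
        assert len(info.indices) == 9 and 3 not in info.indices

    def test_discordant_genotype_excluded_and_counted(self):
        truth = _pair(n=10)
        inferred = truth.copy()
        inferred.hapA[4, 0] = inferred.hapB[4, 0] = 0   # genotype 1 -> 0
        info = informative_sites(truth, inferred, "S0", "1")
        assert 4 not in info.indices and info.n_discordant == 1

    def test_missing_individual_raises(self):
        truth = _pair(n=4)
        with pytest.raises(KeyError):
            informative_sites(truth, truth, "nope", "1")


class TestPhasingYield:
    def test_fully_phased(self):
        truth = _pair(n=10)
        info = informative_sites(truth, truth, "S0", "1")
        assert phasing_yield(info, truth) == 1.0

    def test_97_of_100(self):
        truth = _pair(n=100)
        inferred = truth.copy()
        inferred.phased[:3, 0] = False
        info = informative_sites(truth, inferred, "S0", "1")
        assert phasing_yield(info, inferred) == pytest.approx(0.97)


class TestSwitchErrors:
    def test_identical_zero(self):
        truth = _pair(n=50)
        pr = _profile(truth, truth)
        assert pr.sec == 0 and pr.ser == 0.0

    def test_point_switch_costs_two(self):
        """A phasing error at a single internal marker causes two
        consecutive switch errors."""
        truth = _pair(n=51)
        inferred = truth.copy()
        inferred.hapA[25, 0], inferred.hapB[25, 0] = \
            truth.hapB[25, 0], truth.hapA[25, 0]
        assert _profile(truth, inferred).sec == 2

    def test_tail_flip_costs_one(self):
        truth = _pair(n=50)
        inferred = truth.copy()
        inferred.hapA[30:, 0], inferred.hapB[30:, 0] = \
            truth.hapB[30:, 0], truth.hapA[30:, 0]
        pr = _profile(truth, inferred)
        assert pr.sec == 1
        assert pr.switch_indices.tolist() == [29]

    def test_unphased_sites_skipped_not_breaking_chain(self):
        """Two switches falling inside one unphased gap cancel."""
        truth = _pair(n=9)
        inferred = truth.copy()
        # flip only site 4, then unphase it: the remaining compared chain
        # is unbroken and error-free
        inferred.hapA[4, 0], inferred.hapB[4, 0] = \
            truth.hapB[4, 0], truth.hapA[4, 0]
        inferred.phased[4, 0] = False
        assert _profile(truth, inferred).sec == 0

    def test_ser_uses_informative_denominator(self):
        truth = _pair(n=100)
        inferred = truth.copy()
        inferred.phased[50:, 0] = False
        inferred.hapA[20:, 0], inferred.hapB[20:, 0] = \
            truth.hapB[20:, 0], truth.hapA[20:, 0]
        pr = _profile(truth, inferred)
        assert pr.sec == 1
        assert pr.ser == pytest.approx(1 / 100)       # informative markers
        assert pr.ser_per_pair == pytest.approx(1 / 49)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        """Random <=12-site instances agree exactly with the unordered
        two-locus haplotype-pair enumeration oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        tA, tB, iA, iB, phased = random_phasing_instance(rng, n)
        truth = _pair(tA=tA)
        inferred = make_hapset(iA, iB, phased=phased)
        assert _profile(truth, inferred).sec == \
            oracle_switch_errors(tA, tB, iA, iB, phased)


class TestBlocks:
    def test_single_block_full_yield(self):
        truth = _pair(n=101, positions=np.arange(101) * 100_000)
        bs = build_blocks(_profile(truth, truth))
        assert len(bs.blocks) == 1
        b = bs.blocks[0]
        assert b.raw_length == 10_000_000 and b.qa_length == 10_000_000
        assert b.n_sites == 101 and b.n_phased == 101

    def test_middle_switch_splits_evenly(self):
        truth = _pair(n=101, positions=np.arange(101) * 100_000)
        inferred = truth.copy()
        inferred.hapA[50:, 0], inferred.hapB[50:, 0] = \
            truth.hapB[50:, 0], truth.hapA[50:, 0]
        bs = build_blocks(_profile(truth, inferred))
        assert [b.raw_length for b in bs.blocks] == [4_900_000, 5_000_000]

    def test_block_local_quality_adjustment(self):
        truth = _pair(n=10, positions=np.arange(10) * 1000)
        inferred = truth.copy()
        inferred.phased[1:-1:2, 0] = False     # half the interior unphased
        bs = build_blocks(_profile(truth, inferred))
        b = bs.blocks[0]
        assert b.qa_length == pytest.approx(b.raw_length * b.n_phased
                                            / b.n_sites)
        assert b.n_sites == 10 and b.n_phased == 6

    def test_global_yield_option(self):
        truth = _pair(n=10)
        inferred = truth.copy()
        inferred.phased[3, 0] = False
        pr = _profile(truth, inferred)
        bs = build_blocks(pr, block_local_yield=False)
        assert bs.blocks[0].qa_length == pytest.approx(
            bs.blocks[0].raw_length * 0.9)

    def test_block_count_is_sec_plus_one_at_full_yield(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            tA, tB, iA, iB, _ = random_phasing_instance(rng, n, 0.0)
            truth = _pair(tA=tA)
            pr = _profile(truth, make_hapset(iA, iB))
            bs = build_blocks(pr)
            assert len(bs.blocks) == pr.sec + 1
            assert sum(b.n_phased for b in bs.blocks) == pr.n_compared


class TestQAN:
    def test_single_block(self):
        truth = _pair(n=20, positions=np.arange(20) * 50_000)
        bs = build_blocks(_profile(truth, truth))
        assert qan50([bs]) == bs.blocks[0].qa_length

    def test_two_block_definition(self):
        """Blocks (6 Mb, 60 SNPs) + (4 Mb, 40 SNPs): the top block already
        holds half the SNPs, so QAN50 = 6 Mb."""
        from phaseval.metrics import Block, BlockSet
        blocks = [Block(0, 6_000_000, 60, 60, 6_000_000, 6_000_000.0),
                  Block(7_000_000, 11_000_000, 40, 40, 4_000_000, 4_000_000.0)]
        bs = BlockSet("S0", "1", blocks, 100, 11_000_000)
        assert qan50([bs]) == 6_000_000.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_threshold_scan_oracle(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n = int(rng.integers(4, 80))
        tA, tB, iA, iB, phased = random_phasing_instance(rng, n)
        truth = _pair(tA=tA, positions=np.sort(
            rng.choice(10 ** 7, n, replace=False)))
        inferred = make_hapset(iA, iB, phased=phased,
                               positions=truth.positions)
        bs = build_blocks(_profile(truth, inferred))
        assert qan50([bs]) == oracle_qan50(bs.blocks, bs.n_informative)

    def test_qan_curve_non_increasing(self):
        rng = np.random.default_rng(5)
        tA, tB, iA, iB, phased = random_phasing_instance(rng, 60)
        truth = _pair(tA=tA)
        bs = build_blocks(_profile(truth, make_hapset(iA, iB, phased=phased)))
        curve = qan_curve([bs])
        assert (np.diff(curve["qan_length"]) <= 0).all()

    def test_extra_switch_never_increases_qan50(self):
        rng = np.random.default_rng(6)
        n = 80
        truth = _pair(n=n)
        inferred = truth.copy()
        vals = []
        for cut in (None, 40, 20):
            if cut is not None:
                inferred.hapA[cut:, 0], inferred.hapB[cut:, 0] = \
                    inferred.hapB[cut:, 0].copy(), inferred.hapA[cut:, 0].copy()
            vals.append(qan50([build_blocks(_profile(truth, inferred))]))
        assert vals[0] >= vals[1] >= vals[2]


class TestGenomeFraction:
    def test_full_span_block(self):
        truth = _pair(n=11, positions=np.arange(11) * 1_000_000)
        bs = build_blocks(_profile(truth, truth))
        gf = genome_fraction_in_blocks([bs], thresholds_mb=[1, 5, 10])
        assert (gf["genome_fraction"] == 1.0).all()

    def test_threshold_above_all_blocks(self):
        truth = _pair(n=11, positions=np.arange(11) * 1_000_000)
        bs = build_blocks(_profile(truth, truth))
        gf = genome_fraction_in_blocks([bs], thresholds_mb=[50])
        assert gf["genome_fraction"].iloc[0] == 0.0

    def test_hand_computed_three_blocks(self):
        """Switches at 4 and 7 of 10 uniformly spaced Mb: blocks of 4, 2 and
        2 Mb raw length over a 10-Mb informative span."""
        truth = _pair(n=11, positions=np.arange(11) * 1_000_000)
        inferred = truth.copy()
        for cut in (5, 8):
            inferred.hapA[cut:, 0], inferred.hapB[cut:, 0] = \
                inferred.hapB[cut:, 0].copy(), inferred.hapA[cut:, 0].copy()
        bs = build_blocks(_profile(truth, inferred))
        assert [b.raw_length for b in bs.blocks] == \
            [4_000_000, 2_000_000, 2_000_000]
        gf = genome_fraction_in_blocks([bs], thresholds_mb=[1, 3])
        assert gf["genome_fraction"].tolist() == \
            pytest.approx([0.8, 0.4])


class TestPairwise:
    def test_error_free_probability_one(self):
        truth = _pair(n=200, positions=np.arange(200) * 10_000)
        curve = pairwise_accuracy([_profile(truth, truth)],
                                  distances_mb=[0.01, 0.1, 1.0])
        assert (curve["accuracy"].dropna() == 1.0).all()

    def test_matches_enumeration_oracle(self):
        """Single middle switch on a uniform 100-site chromosome: per-bin
        probabilities equal full pair enumeration."""
        truth = _pair(n=100, positions=np.arange(100) * 100_000)
        inferred = truth.copy()
        inferred.hapA[50:, 0], inferred.hapB[50:, 0] = \
            truth.hapB[50:, 0], truth.hapA[50:, 0]
        pr = _profile(truth, inferred)
        for d in (0.5, 1.0, 3.0):
            lo, hi = d * 1e6 * 0.9, d * 1e6 * 1.1
            total, correct = oracle_pairwise(pr.compared_positions,
                                             pr.orientation, lo, hi)
            curve = pairwise_accuracy([pr], distances_mb=[d], tolerance=0.1)
            assert curve["n_pairs"].iloc[0] == total
            assert curve["accuracy"].iloc[0] == pytest.approx(correct / total)

    def test_adjacent_bin_identity(self):
        """Accuracy over exactly-adjacent compared pairs equals
        1 - SEC / (number of compared pairs)."""
        rng = np.random.default_rng(9)
        tA, tB, iA, iB, _ = random_phasing_instance(rng, 300, 0.0)
        truth = _pair(tA=tA, positions=np.arange(300) * 1000)
        pr = _profile(truth, make_hapset(iA, iB, positions=truth.positions))
        curve = pairwise_accuracy([pr], distances_mb=[0.001], tolerance=0.0)
        n_pairs = pr.n_compared - 1
        assert curve["n_pairs"].iloc[0] == n_pairs
        assert curve["accuracy"].iloc[0] == \
            pytest.approx(1 - pr.sec / n_pairs)

    def test_empty_bin_is_missing(self):
        truth = _pair(n=10, positions=np.arange(10) * 100)
        curve = pairwise_accuracy([_profile(truth, truth)],
                                  distances_mb=[50.0])
        assert np.isnan(curve["accuracy"].iloc[0])


class TestOrientationFlipInvariance:
    @pytest.mark.parametrize("flip_truth", [False, True])
    def test_global_flip_leaves_metrics_unchanged(self, flip_truth):
        rng = np.random.default_rng(11)
        tA, tB, iA, iB, phased = random_phasing_instance(rng, 120)
        truth = _pair(tA=tA, positions=np.arange(120) * 10_000)
        inferred = make_hapset(iA, iB, phased=phased,
                               positions=truth.positions)
        base = _profile(truth, inferred)
        flipped = (truth if flip_truth else inferred).copy()
        flipped.hapA, flipped.hapB = flipped.hapB.copy(), flipped.hapA.copy()
        pr2 = _profile(flipped if flip_truth else truth,
                       inferred if flip_truth else flipped)
        assert pr2.sec == base.sec
        assert np.array_equal(pr2.switch_indices, base.switch_indices)
        assert qan50([build_blocks(pr2)]) == qan50([build_blocks(base)])


class TestEvaluate:
    def test_perfect_inference(self, small_sim):
        rep = pv.evaluate(small_sim.truth_haps, small_sim.truth_haps)
        assert (rep.per_individual["sec"] == 0).all()
        assert (rep.per_individual["yield"] == 1.0).all()

    def test_corruption_log_oracle(self, small_sim):
        """Per-individual SEC equals the parity count of logged long
        switches between consecutive compared sites."""
        corrupted, log = pv.corrupt_haplotypes(
            small_sim.truth_haps, long_switch_rate_per_Mb=0.3, seed=31)
        rep = pv.evaluate(small_sim.truth_haps, corrupted)
        for pr in rep.profiles:
            ev = log[(log["individual"] == pr.individual)
                     & (log["chrom"] == pr.chrom)
                     & (log["kind"] == "long_switch")]
            bp = np.sort(ev["position"].to_numpy())
            seg = np.searchsorted(bp, pr.compared_positions, side="left")
            expected = int((np.diff(seg) % 2 == 1).sum())
            assert pr.sec == expected

    def test_point_switch_rate_gives_double_ser(self):
        """Isolated point switches each cost two switch errors, so
        SER ~ 2q for per-site flip rate q."""
        n = 200_000
        truth = _pair(n=n, positions=np.arange(n) * 1000)
        q = 0.001
        corrupted, _ = pv.corrupt_haplotypes(truth,
                                             point_switch_rate_per_site=q,
                                             seed=33)
        pr = _profile(truth, corrupted)
        se = np.sqrt(2 * q / n)      # ~Poisson count fluctuation
        assert pr.ser == pytest.approx(2 * q, abs=4 * se)

    def test_mismatched_axes_rejected(self, small_sim):
        other = _pair(n=4)
        with pytest.raises(ValueError):
            pv.evaluate(small_sim.truth_haps, other)

    def test_conservation_sums(self, small_sim):
        corrupted, _ = pv.corrupt_haplotypes(small_sim.truth_haps, 0.2, 1e-3,
                                             0.05, seed=35)
        rep = pv.evaluate(small_sim.truth_haps, corrupted)
        for pr, bs in zip(rep.profiles, rep.blocksets):
            assert sum(b.n_phased for b in bs.blocks) == pr.n_compared
            assert sum(b.raw_length for b in bs.blocks) <= bs.informative_span
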