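"""Phasing-accuracy metrics against a trio-derived gold standard.

All metrics are computed with respect to *informative* sites: heterozygous
and phased in the true haplotypes, with concordant genotypes in the
evaluated set. Per individual and chromosome:

* **yield** — fraction of informative sites the evaluated method phased;
* **SEC/SER** — switch errors: changes of orientation (same vs flipped
  relative to truth) between consecutive phased informative sites; the rate
  divides the count by the number of informative markers;
* **QA blocks** — maximal runs of constant orientation; the quality-adjusted
  length multiplies the bp span by the fraction of the block's informative
  sites that are phased;
* **QAN50** — the largest QA length L such that half of all informative
  SNPs lie in blocks with QA length >= L;
* **pairwise accuracy** — probability that two informative sites at a given
  distance have no phasing error between them (an even number of
  intervening switches).

Sites the evaluated method left unphased are skipped without breaking the
consecutive-site chain: their penalty flows through the yield and the QA
multiplier instead of the switch count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import HaplotypeSet

log = logging.getLogger(__name__)

__all__ = ["InformativeSiteSet", "SwitchProfile", "Block", "BlockSet",
           "informative_sites", "phasing_yield", "count_switch_errors",
           "build_blocks", "qan_curve", "genome_fraction_in_blocks",
           "pairwise_accuracy", "evaluate", "EvalReport",
           "DEFAULT_DISTANCES_MB", "DEFAULT_LENGTH_THRESHOLDS_MB"]

DEFAULT_DISTANCES_MB = (0.01, 0.1, 1.0, 2.0, 5.0, 10.0, 50.0)
DEFAULT_LENGTH_THRESHOLDS_MB = (1.0, 5.0, 10.0, 50.0)


@dataclass
class InformativeSiteSet:
    individual: str
    chrom: str
    indices: np.ndarray           # variant indices within the chromosome slice
    positions: np.ndarray         # bp
    n_discordant: int             # genotype mismatches truth vs inferred
    n_missing: int                # inferred genotype missing at truth-phased hets


@dataclass
class SwitchProfile:
    individual: str
    chrom: str
    info_positions: np.ndarray        # all informative sites (bp)
    compared_positions: np.ndarray    # informative AND inferred-phased (bp)
    orientation: np.ndarray           # bool per compared site: True = same
    switch_indices: np.ndarray        # i: switch between compared sites i, i+1
    degenerate: bool = False          # fewer than 2 compared sites

    @property
    def sec(self) -> int:
        return len(self.switch_indices)

    @property
    def n_informative(self) -> int:
        return len(self.info_positions)

    @property
    def n_compared(self) -> int:
        return len(self.compared_positions)

    @property
    def ser(self) -> float:
        return self.sec / self.n_informative if self.n_informative else np.nan

    @property
    def ser_per_pair(self) -> float:
        return self.sec / (self.n_compared - 1) if self.n_compared > 1 else np.nan

    @property
    def phasing_yield(self) -> float:
        return self.n_compared / self.n_informative if self.n_informative else np.nan


@dataclass(frozen=True)
class Block:
    start: int                    # bp of first compared site
    end: int                      # bp of last compared site
    n_sites: int                  # informative sites within [start, end]
    n_phased: int                 # compared sites in the run
    raw_length: int               # end - start (0 for singleton blocks)
    qa_length: float              # raw_length x (n_phased / n_sites)


@dataclass
class BlockSet:
    individual: str
    chrom: str
    blocks: list[Block]
    n_informative: int
    informative_span: int         # bp, first to last informative site


def informative_sites(truth: HaplotypeSet, inferred: HaplotypeSet,
                      individual: str, chrom: str) -> InformativeSiteSet:
    """Sites heterozygous and phased in the truth with concordant inferred
    genotype. Discordant and missing inferred genotypes are excluded and
    counted separately (orientation is undefined there)."""
    for hs in (truth, inferred):
        if individual not in hs.sample_ids:
            raise KeyError(f"individual {individual!r} absent")
    sl = truth.chrom_slice(chrom)
    jt = truth.sample_index(individual)
    ji = inferred.sample_index(individual)
    tA, tB = truth.hapA[sl, jt], truth.hapB[sl, jt]
    t_gt = tA + tB
    het = truth.phased[sl, jt] & (tA != tB) & (tA >= 0) & (tB >= 0)
    iA, iB = inferred.hapA[sl, ji], inferred.hapB[sl, ji]
    i_missing = (iA < 0) | (iB < 0)
    i_gt = np.where(i_missing, -1, iA + iB)
    concordant = het & ~i_missing & (i_gt == t_gt)
    n_discordant = int((het & ~i_missing & (i_gt != t_gt)).sum())
    n_missing = int((het & i_missing).sum())
    idx = np.flatnonzero(concordant)
    return InformativeSiteSet(individual, chrom, idx,
                              truth.positions[sl][idx], n_discordant, n_missing)


def phasing_yield(info: InformativeSiteSet, inferred: HaplotypeSet) -> float:
    """Fraction of informative sites phased by the evaluated method
    (NaN when the informative set is empty)."""
    if len(info.indices) == 0:
        log.warning("no informative sites for %s on %s",
                    info.individual, info.chrom)
        return np.nan
    sl = inferred.chrom_slice(info.chrom)
    j = inferred.sample_index(info.individual)
    return float(inferred.phased[sl, j][info.indices].mean())


def count_switch_errors(truth: HaplotypeSet, inferred: HaplotypeSet,
                        individual: str, chrom: str,
                        info: InformativeSiteSet | None = None
                        ) -> SwitchProfile:
    """Orientation per phased informative site and switches between
    consecutive ones. Unphased sites are skipped without breaking the
    chain; two switch events inside one skipped gap cancel."""
    if info is None:
        info = informative_sites(truth, inferred, individual, chrom)
    sl = truth.chrom_slice(chrom)
    jt = truth.sample_index(individual)
    ji = inferred.sample_index(individual)
    idx = info.indices
    ph = inferred.phased[sl, ji][idx]
    cmp_idx = idx[ph]
    same = inferred.hapA[sl, ji][cmp_idx] == truth.hapA[sl, jt][cmp_idx]
    # concordant het sites are either identical or swapped; anything else
    # must have been excluded upstream
    assert np.array_equal(
        inferred.hapB[sl, ji][cmp_idx] == truth.hapB[sl, jt][cmp_idx], same)
    switches = np.flatnonzero(same[:-1] != same[1:])
    return SwitchProfile(individual, chrom, info.positions,
                         truth.positions[sl][cmp_idx], same, switches,
                         degenerate=len(cmp_idx) < 2)


def build_blocks(profile: SwitchProfile, block_local_yield: bool = True
                 ) -> BlockSet:
    """Maximal runs of constant orientation, bounded by switches and the
    chromosome's first/last compared site.

    Raw length is the first-to-last compared-site distance (switch gaps are
    assigned to neither block). The QA multiplier is the fraction of the
    block's informative sites that are phased — block-local by default, the
    chromosome-wide yield with ``block_local_yield=False``.
    """
    blocks: list[Block] = []
    cpos, ipos = profile.compared_positions, profile.info_positions
    n_info = len(ipos)
    span = int(ipos[-1] - ipos[0]) if n_info else 0
    if len(cpos):
        bounds = np.concatenate([[0], profile.switch_indices + 1, [len(cpos)]])
        global_yield = profile.phasing_yield
        for s, e in zip(bounds[:-1], bounds[1:]):
            start, end = int(cpos[s]), int(cpos[e - 1])
            n_sites = int(np.searchsorted(ipos, end, side="right")
                          - np.searchsorted(ipos, start, side="left"))
            n_phased = int(e - s)
            raw = end - start
            factor = (n_phased / n_sites) if block_local_yield else global_yield
            blocks.append(Block(start, end, n_sites, n_phased, raw,
                                raw * factor))
    return BlockSet(profile.individual, profile.chrom, blocks, n_info, span)


def _pooled_blocks(blocksets: Sequence[BlockSet]) -> tuple[np.ndarray, ...]:
    qa = np.array([b.qa_length for bs in blocksets for b in bs.blocks])
    raw = np.array([b.raw_length for bs in blocksets for b in bs.blocks])
    nsites = np.array([b.n_sites for bs in blocksets for b in bs.blocks])
    nphased = np.array([b.n_phased for bs in blocksets for b in bs.blocks])
    return qa, raw, nsites, nphased


def qan_curve(blocksets: Sequence[BlockSet],
              x_grid: Sequence[float] = tuple(range(5, 100, 5)),
              ) -> pd.DataFrame:
    """QANx for a grid of x: blocks sorted by QA length descending, QANx is
    the QA length of the block at which the cumulative informative-SNP
    fraction first reaches x%. Also reports the SNP count of that block.
    The fraction denominator is the total number of informative sites, so
    QANx is 0 where unphased sites prevent the cumulative fraction from
    reaching x%."""
    qa, _, nsites, _ = _pooled_blocks(blocksets)
    total = sum(bs.n_informative for bs in blocksets)
    order = np.argsort(-qa, kind="stable")
    qa_sorted = qa[order]
    cum = np.cumsum(nsites[order]) / total if total else np.array([])
    rows = []
    for x in x_grid:
        hit = np.flatnonzero(cum >= x / 100.0)
        if hit.size:
            i = hit[0]
            rows.append({"x": x, "qan_length": float(qa_sorted[i]),
                         "qan_snps": int(nsites[order][i])})
        else:
            rows.append({"x": x, "qan_length": 0.0, "qan_snps": 0})
    return pd.DataFrame(rows)


def qan50(blocksets: Sequence[BlockSet]) -> float:
    return float(qan_curve(blocksets, x_grid=[50])["qan_length"].iloc[0])


def genome_fraction_in_blocks(blocksets: Sequence[BlockSet],
                              thresholds_mb: Sequence[float]
                              = DEFAULT_LENGTH_THRESHOLDS_MB) -> pd.DataFrame:
    """For each minimal QA length L: fraction of the informative span
    covered by (raw lengths of) blocks with QA length >= L."""
    if any(t <= 0 for t in thresholds_mb):
        raise ValueError("thresholds must be positive")
    qa, raw, _, _ = _pooled_blocks(blocksets)
    denom = sum(bs.informative_span for bs in blocksets)
    rows = []
    for t in thresholds_mb:
        num = raw[qa >= t * 1e6].sum() if len(qa) else 0.0
        rows.append({"min_qa_length_mb": t,
                     "genome_fraction": float(num / denom) if denom else np.nan})
    return pd.DataFrame(rows)


def pairwise_accuracy(profiles: Sequence[SwitchProfile],
                      distances_mb: Sequence[float] = DEFAULT_DISTANCES_MB,
                      tolerance: float = 0.10,
                      max_pairs: int | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Probability of no phasing error between pairs of compared sites
    whose separation lies within ``±tolerance`` (relative) of each target
    distance. A pair is correct iff its two sites have equal orientation
    (an even number of switches in between).

    Pairs are counted exhaustively per profile with prefix sums (linear
    time), so no subsampling is needed; ``max_pairs``/``seed`` are accepted
    for API stability and trigger plain per-profile subsampling only when
    ``max_pairs`` is set and exceeded.
    """
    if any(d <= 0 for d in distances_mb):
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for d in distances_mb:
        lo, hi = d * 1e6 * (1 - tolerance), d * 1e6 * (1 + tolerance)
        total = 0
        correct = 0
        for pr in profiles:
            pos = pr.compared_positions
            if len(pos) < 2:
                continue
            o = pr.orientation.astype(np.int64)
            cum = np.concatenate([[0], np.cumsum(o)])
            j_lo = np.searchsorted(pos, pos + lo, side="left")
            j_hi = np.searchsorted(pos, pos + hi, side="right")
            n_j = np.maximum(j_hi - j_lo, 0)
            n_true = cum[j_hi] - cum[j_lo]
            match = np.where(o == 1, n_true, n_j - n_true)
            if max_pairs is not None and n_j.sum() > max_pairs:
                keep = rng.random(len(pos)) < max_pairs / n_j.sum()
                n_j, match = n_j[keep], match[keep]
            total += int(n_j.sum())
            correct += int(match.sum())
        if total == 0:
            log.warning("no site pairs near %.3g Mb", d)
            out.append({"distance_mb": d, "n_pairs": 0, "accuracy": np.nan})
        else:
            out.append({"distance_mb": d, "n_pairs": total,
                        "accuracy": correct / total})
    return pd.DataFrame(out)


@dataclass
class EvalReport:
    per_individual: pd.DataFrame
    summary: dict
    qan: pd.DataFrame
    genome_fraction: pd.DataFrame
    pairwise: pd.DataFrame
    profiles: list[SwitchProfile] = field(repr=False, default_factory=list)
    blocksets: list[BlockSet] = field(repr=False, default_factory=list)


def _summary_stats(s: pd.Series) -> dict:
    if len(s) == 0:
        return {}
    return {"min": float(s.min()), "mean": float(s.mean()),
            "median": float(s.median()), "max": float(s.max())}


def evaluate(truth: HaplotypeSet, inferred: HaplotypeSet,
             individuals: Sequence[str] | None = None,
             distances_mb: Sequence[float] = DEFAULT_DISTANCES_MB,
             thresholds_mb: Sequence[float] = DEFAULT_LENGTH_THRESHOLDS_MB,
             block_local_yield: bool = True,
             pairwise_tolerance: float = 0.10) -> EvalReport:
    """Full evaluation of an inferred haplotype set against the truth.

    ``individuals`` restricts the evaluation cohort (e.g. the validation
    offspring); by default the intersection of the two sample sets is used.
    Medians across individuals use the standard midpoint convention.
    """
    if not np.array_equal(truth.positions, inferred.positions) or \
            not np.array_equal(truth.chroms, inferred.chroms):
        raise ValueError("truth and inferred must share the same variant axes")
    common = [s for s in truth.sample_ids if s in set(inferred.sample_ids)]
    if individuals is not None:
        missing = [i for i in individuals if i not in common]
        if missing:
            log.warning("%d requested individuals missing from inputs",
                        len(missing))
        common = [i for i in individuals if i in common]
    if not common:
        raise ValueError("no overlapping individuals to evaluate")

    profiles: list[SwitchProfile] = []
    blocksets: list[BlockSet] = []
    rows = []
    chroms = truth.chromosomes()
    for ind in common:
        ind_profiles = []
        ind_blocks = []
        n_disc = n_miss = 0
        for c in chroms:
            info = informative_sites(truth, inferred, ind, c)
            n_disc += info.n_discordant
            n_miss += info.n_missing
            pr = count_switch_errors(truth, inferred, ind, c, info=info)
            ind_profiles.append(pr)
            ind_blocks.append(build_blocks(pr, block_local_yield))
        profiles.extend(ind_profiles)
        blocksets.extend(ind_blocks)
        n_info = sum(p.n_informative for p in ind_profiles)
        n_cmp = sum(p.n_compared for p in ind_profiles)
        sec = sum(p.sec for p in ind_profiles)
        qa = [b.qa_length for bs in ind_blocks for b in bs.blocks]
        rows.append({
            "individual": ind,
            "n_informative": n_info, "n_compared": n_cmp,
            "n_discordant": n_disc, "n_missing": n_miss,
            "sec": sec,
            "ser": sec / n_info if n_info else np.nan,
            "yield": n_cmp / n_info if n_info else np.nan,
            "qa_block_min": float(np.min(qa)) if qa else np.nan,
            "qa_block_mean": float(np.mean(qa)) if qa else np.nan,
            "qa_block_median": float(np.median(qa)) if qa else np.nan,
            "qa_block_max": float(np.max(qa)) if qa else np.nan,
            "qan50": qan50(ind_blocks),
        })
    per_ind = pd.DataFrame(rows)
    summary = {"n_individuals": len(common)}
    for metric in ("sec", "ser", "yield", "qan50", "qa_block_mean",
                   "qa_block_median"):
        summary[metric] = _summary_stats(per_ind[metric].dropna())
    return EvalReport(
        per_individual=per_ind, summary=summary,
        qan=qan_curve(blocksets),
        genome_fraction=genome_fraction_in_blocks(blocksets, thresholds_mb),
        pairwise=pairwise_accuracy(profiles, distances_mb,
                                   tolerance=pairwise_tolerance),
        profiles=profiles, blocksets=blocksets)
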