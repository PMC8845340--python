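"""Region-level exclusion: chromosome ends, high-coverage windows, and
map-error detection from recombination peaks and inheritance-vector
correlation.

A block of markers whose assembly placement is wrong shows up as a small
region flanked by two intervals of implausibly high recombination rate
(> 0.05 per meiosis): every meiosis appears to recombine across the
displaced junctions. A genuine recombination hotspot also elevates interval
rates, but the within-family segregation pattern (parental origin per
meiosis) inside the region stays consistent with its flanks; a misplaced
block segregates independently. The squared correlation across meioses
between region and flank majority origins separates the two cases
(flag when r-squared < 0.90). The procedure iterates — masking flagged
markers and recomputing rates — until no new evidence of map errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .crossover import CrossoverCall, OriginVector, call_crossovers
from .model import RegionMask

log = logging.getLogger(__name__)

__all__ = ["IntervalRateTrack", "interval_recombination_rates",
           "flag_map_error_regions", "flag_high_coverage_regions",
           "build_exclusion_mask"]


@dataclass
class IntervalRateTrack:
    """Recombination rate per adjacent-marker interval: fractional crossover
    events assigned to the interval divided by the number of meioses."""

    chrom: str
    positions: np.ndarray         # n marker bp
    counts: np.ndarray            # n-1 fractional CO counts
    n_meioses: int

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.n_meioses


def interval_recombination_rates(calls: Sequence[CrossoverCall],
                                 positions: np.ndarray, chrom: str,
                                 n_meioses: int) -> IntervalRateTrack:
    """Distribute each call uniformly over the marker intervals its
    localization interval spans (1/m per interval — unbiased under uniform
    localization uncertainty), then divide by the meiosis count."""
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    positions = np.asarray(positions)
    counts = np.zeros(max(len(positions) - 1, 0))
    for c in calls:
        if c.chrom != chrom:
            continue
        i = int(np.searchsorted(positions, c.start, side="left"))
        j = int(np.searchsorted(positions, c.end, side="left"))
        if j <= i:
            continue
        counts[i:j] += 1.0 / (j - i)
    return IntervalRateTrack(chrom, positions, counts, n_meioses)


def _majority_origin(ov: OriginVector, lo: float, hi: float) -> float:
    """Majority origin of one meiosis over [lo, hi] bp, coded 0/1; NaN when
    no informative site falls inside."""
    sel = (ov.positions >= lo) & (ov.positions <= hi)
    if not sel.any():
        return np.nan
    return float(np.round(np.mean(ov.origins[sel] - 1)))


def _flank_majorities(ov: OriginVector, lo: float, hi: float,
                      n_sites: int) -> tuple[float, float]:
    left = ov.origins[ov.positions < lo][-n_sites:] - 1
    right = ov.origins[ov.positions > hi][:n_sites] - 1
    return (float(np.round(np.mean(left))) if len(left) else np.nan,
            float(np.round(np.mean(right))) if len(right) else np.nan)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        # degenerate: identical (or constant) segregation -> fully
        # consistent with flanks
        return 1.0 if len(x) and np.array_equal(x, y) else np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def flag_map_error_regions(origin_vectors: Sequence[OriginVector],
                           r2_threshold: float = 0.90,
                           rate_threshold: float = 0.05,
                           max_span: int = 1_000_000,
                           flank_sites: int = 50,
                           min_meioses: int = 20,
                           min_support: int = 3,
                           max_iter: int = 10,
                           ) -> tuple[RegionMask, pd.DataFrame]:
    """Iteratively flag candidate map-error regions.

    Candidates are marker runs bounded by two adjacent-marker intervals with
    recombination rate above ``rate_threshold`` and spanning at most
    ``max_span`` bp. A candidate is flagged when the squared correlation
    (across the non-recombinant meioses, i.e. those whose two flanks agree)
    between within-region and flanking majority origins falls below
    ``r2_threshold``. Terminal intervals above
    the rate threshold flag the chromosome extremity outright. After each
    pass the flagged markers are removed, crossovers re-called and rates
    recomputed, until no new flags appear.

    Returns the mask and a report of candidate regions with their rates and
    r-squared values.
    """
    by_chrom: dict[str, list[OriginVector]] = {}
    for ov in origin_vectors:
        by_chrom.setdefault(ov.chrom, []).append(ov)

    flagged: list[tuple[str, int, int]] = []
    rows: list[dict] = []
    for chrom, ovs in by_chrom.items():
        all_pos = np.unique(np.concatenate([ov.positions for ov in ovs])) \
            if ovs else np.array([], dtype=np.int64)
        active = np.ones(len(all_pos), dtype=bool)
        n_meioses = len({(ov.parent, ov.child) for ov in ovs})
        for _it in range(max_iter):
            pos = all_pos[active]
            if len(pos) < 3:
                break
            cur = [ov.restrict(pos) for ov in ovs]
            calls = [c for ov in cur
                     for c in call_crossovers(ov, min_support)]
            track = interval_recombination_rates(calls, pos, chrom, n_meioses)
            hot = np.flatnonzero(track.rates > rate_threshold)
            new: list[tuple[int, int]] = []
            # terminal intervals: flag the extremity marker run
            if hot.size and hot[0] == 0:
                new.append((0, 0))
            if hot.size and hot[-1] == len(pos) - 2:
                new.append((len(pos) - 1, len(pos) - 1))
            for a, b in zip(hot, hot[1:]):
                lo_i, hi_i = a + 1, b          # marker run between hot intervals
                lo, hi = pos[lo_i], pos[hi_i]
                if hi - lo > max_span:
                    continue
                region = np.array([_majority_origin(ov, lo, hi) for ov in cur])
                lr = np.array([_flank_majorities(ov, lo, hi, flank_sites)
                               for ov in cur])
                # restrict to the non-recombinant majority: meioses whose two
                # flanks agree (no crossover across the candidate span) — for
                # a genuine hotspot these meioses keep region == flanks, for a
                # misplaced block the region still segregates independently
                flank = np.where(lr[:, 0] == lr[:, 1], lr[:, 0], np.nan)
                complete = int((~np.isnan(region) & ~np.isnan(flank)).sum())
                if complete < min_meioses:
                    log.warning("candidate %s:%d-%d skipped: only %d "
                                "informative meioses", chrom, lo, hi, complete)
                    continue
                r2 = _r_squared(region, flank)
                rows.append({"chrom": chrom, "start": int(lo), "end": int(hi),
                             "left_rate": float(track.rates[a]),
                             "right_rate": float(track.rates[b]),
                             "n_meioses": complete, "r2": r2})
                if not np.isnan(r2) and r2 < r2_threshold:
                    new.append((lo_i, hi_i))
            if not new:
                break
            for lo_i, hi_i in new:
                flagged.append((chrom, int(pos[lo_i]), int(pos[hi_i]) + 1))
                idx = np.searchsorted(all_pos, pos[lo_i:hi_i + 1])
                active[idx] = False
    report = pd.DataFrame(rows, columns=["chrom", "start", "end", "left_rate",
                                         "right_rate", "n_meioses", "r2"])
    return RegionMask(flagged), report


def flag_high_coverage_regions(depth_track: pd.DataFrame,
                               factor: float = 6.0) -> RegionMask:
    """Windows with depth above ``factor`` times the individual's own mean
    depth, flagged per individual and unioned across individuals."""
    if depth_track.empty:
        raise ValueError("empty depth track")
    intervals: list[tuple[str, int, int]] = []
    for _, sub in depth_track.groupby("individual"):
        mean = sub["depth"].mean()
        high = sub[sub["depth"] > factor * mean]
        intervals.extend((r.chrom, int(r.start), int(r.end))
                         for r in high.itertuples(index=False))
    return RegionMask(intervals)


def build_exclusion_mask(chrom_lengths: dict[str, int],
                         *masks: RegionMask,
                         end_trim_bp: int = 10_000) -> RegionMask:
    """Union of the first/last ``end_trim_bp`` of every chromosome with any
    additional masks, merged."""
    if end_trim_bp < 0:
        raise ValueError("end_trim_bp must be >= 0")
    intervals: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if 2 * end_trim_bp >= length:
            log.warning("end trim covers all of chromosome %s", chrom)
            intervals.append((chrom, 0, length))
        elif end_trim_bp > 0:
            intervals.append((chrom, 0, end_trim_bp))
            intervals.append((chrom, length - end_trim_bp, length))
    return RegionMask(intervals).union(*masks)
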