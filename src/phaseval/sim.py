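"""Pedigree genotype/haplotype simulator with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a trio-rich cattle-style pedigree (264 individuals including 98
offspring with both parents present, by default), biallelic SNPs, Poisson
recombination over a genetic map totalling ~24.5 Morgans genome-wide with
sex-specific rates (26/24.5 male, 23/24.5 female), genotyping error,
missingness, non-Mendelian artifact variants and misplaced-marker blocks.

Crossovers are drawn without interference (pure Poisson on the cM scale);
the expectation arguments downstream use map length only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import (MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap,
                    Pedigree, PedigreeRecord)

__all__ = [
    "SimConfig", "SimTruth", "build_pedigree", "simulate_founder_haplotypes",
    "simulate_gamete", "simulate_dataset", "corrupt_haplotypes",
    "inject_artifact_variants", "inject_map_errors", "simulate_depth_track",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults state a genome of 29 autosomes totalling ~2.5 Gb and 24.5
    Morgans (sex-averaged), and a pedigree of 264 individuals: 83 founders,
    83 duo offspring (exactly one parent in the sample) and 98 trio
    offspring, giving 98 trios and 279 genotyped parent-offspring pairs.
    Male/female crossover-rate multipliers are 26/24.5 and 23/24.5 so
    expected genome-wide crossover counts per meiosis are 26 and 23.
    Marker density and noise rates are analysis choices, not population
    facts, and default to modest/clean values.
    """

    n_chrom: int = 29
    chrom_bp_length: int = 86_600_000
    chrom_cM_length: float = 2450.0 / 29
    n_variants_per_chrom: int = 1000
    freq_range: tuple[float, float] = (0.05, 0.95)
    ld_copy_prob: float = 0.0
    n_founders: int = 83
    n_duos: int = 83
    n_trios: int = 98
    male_scale: float = 26 / 24.5
    female_scale: float = 23 / 24.5
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ld_copy_prob", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_chrom, self.chrom_bp_length, self.n_variants_per_chrom,
               self.n_founders, self.n_trios) <= 0 or self.n_duos < 0:
            raise ValueError("counts must be positive")
        if self.chrom_cM_length < 0:
            raise ValueError("cM length must be >= 0")
        lo, hi = self.freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("freq_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_founders < 2:
            raise ValueError("need at least one male and one female founder")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Simulator output: ground truth plus the observed (noisy) genotypes.

    ``co_log[(parent, child)][chrom]`` holds the true crossover bp positions
    of that meiosis. ``corruption_log`` records switch/unphase events added
    by :func:`corrupt_haplotypes`; ``artifact_flags`` marks injected
    non-Mendelian variants; ``relocations`` records misplaced marker blocks.
    """

    config: SimConfig
    pedigree: Pedigree
    marker_map: MarkerMap
    freqs: np.ndarray
    truth_haps: HaplotypeSet
    observed: GenotypeMatrix
    co_log: dict[tuple[str, str], dict[str, np.ndarray]]
    corruption_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    artifact_flags: np.ndarray | None = None
    relocations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.truth_haps.n_variants, dtype=bool)


def build_pedigree(config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Founders (half male, half female), duo offspring with one sampled
    parent, and trio offspring whose parents are drawn with replacement from
    founders and duo offspring — sires and dams are reused, as in cattle."""
    n_m = config.n_founders // 2
    founders = []
    for i in range(config.n_founders):
        sex = "male" if i < n_m else "female"
        founders.append(PedigreeRecord(f"F{i:04d}", None, None, sex))
    f_males = [r.individual for r in founders if r.sex == "male"]
    f_females = [r.individual for r in founders if r.sex == "female"]
    duos = []
    for k in range(config.n_duos):
        if rng.random() < 0.5 and f_males:
            sire, dam = f_males[rng.integers(len(f_males))], None
        else:
            sire, dam = None, f_females[rng.integers(len(f_females))]
        sex = "male" if rng.random() < 0.5 else "female"
        duos.append(PedigreeRecord(f"D{k:04d}", sire, dam, sex))
    parents = founders + duos
    males = [r.individual for r in parents if r.sex == "male"]
    females = [r.individual for r in parents if r.sex == "female"]
    offspring = []
    for k in range(config.n_trios):
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        sex = "male" if rng.random() < 0.5 else "female"
        offspring.append(PedigreeRecord(f"C{k:04d}", sire, dam, sex))
    return Pedigree(founders + duos + offspring)


def build_marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Random marker positions per chromosome; cM linear in bp."""
    chroms, positions, cms = [], [], []
    for c in config.chrom_names:
        pos = np.sort(rng.choice(config.chrom_bp_length,
                                 size=config.n_variants_per_chrom,
                                 replace=False))
        chroms.extend([c] * len(pos))
        positions.append(pos)
        cms.append(pos / config.chrom_bp_length * config.chrom_cM_length)
    return MarkerMap(np.array(chroms, dtype=object),
                     np.concatenate(positions), np.concatenate(cms))


def _draw_population_haps(config: SimConfig, n_haps: int, freqs: np.ndarray,
                          marker_map: MarkerMap, rng: np.random.Generator
                          ) -> np.ndarray:
    """(n_var, n_haps) haplotypes: site i allele ~ Bernoulli(freq_i), except
    that with probability ``ld_copy_prob`` a site copies the previous site's
    allele on the same haplotype (a crude long-range-LD stand-in)."""
    n_var = len(marker_map.positions)
    haps = (rng.random((n_var, n_haps)) < freqs[:, None]).astype(np.int8)
    q = config.ld_copy_prob
    if q > 0:
        copy = rng.random((n_var, n_haps)) < q
        for c in dict.fromkeys(marker_map.chroms):
            sel = np.flatnonzero(marker_map.chroms == c)
            for i in sel[1:]:
                row_copy = copy[i]
                haps[i, row_copy] = haps[i - 1, row_copy]
    return haps


def simulate_founder_haplotypes(config: SimConfig, n_founders: int,
                                rng: np.random.Generator | None = None,
                                freqs: np.ndarray | None = None,
                                marker_map: MarkerMap | None = None,
                                sample_ids: Sequence[str] | None = None,
                                ) -> tuple[HaplotypeSet, np.ndarray]:
    """Draw ``2 * n_founders`` haplotypes site-wise from per-site allele
    frequencies, optionally with first-order copy dependence between
    neighbouring sites (``ld_copy_prob``). Returns (haplotypes, freqs)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if marker_map is None:
        marker_map = build_marker_map(config, rng)
    n_var = len(marker_map.positions)
    if freqs is None:
        lo, hi = config.freq_range
        freqs = rng.uniform(lo, hi, size=n_var)
    haps = _draw_population_haps(config, 2 * n_founders, freqs, marker_map, rng)
    if sample_ids is None:
        sample_ids = [f"F{i:04d}" for i in range(n_founders)]
    hs = HaplotypeSet(marker_map.chroms, marker_map.positions, list(sample_ids),
                      haps[:, 0::2], haps[:, 1::2],
                      np.ones((n_var, n_founders), dtype=bool))
    return hs, freqs


def simulate_gamete(parent_hapA: np.ndarray, parent_hapB: np.ndarray,
                    positions: np.ndarray, cM: np.ndarray, sex_scale: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis on one chromosome.

    Crossover count ~ Poisson(cM length / 100 x sex_scale); positions are
    uniform on the cM scale and mapped to bp by linear interpolation. The
    gamete copies one parental haplotype, switching source at each
    crossover; the starting haplotype is chosen uniformly. Returns
    (gamete alleles, sorted crossover bp positions).
    """
    if len(positions) == 0:
        raise ValueError("cannot simulate a gamete over zero markers")
    morgans = (cM[-1] - cM[0]) / 100.0 * sex_scale
    n_co = rng.poisson(morgans)
    co_cm = np.sort(rng.uniform(cM[0], cM[-1], size=n_co))
    co_bp = np.interp(co_cm, cM, positions.astype(float))
    start = int(rng.integers(2))
    # markers strictly after a crossover take the other haplotype
    hap_idx = (start + np.searchsorted(co_bp, positions, side="left")) % 2
    gamete = np.where(hap_idx == 0, parent_hapA, parent_hapB).astype(np.int8)
    return gamete, co_bp.astype(np.int64)


def _apply_noise(calls: np.ndarray, error_rate: float, missing_rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    out = calls.copy()
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        # replace by a uniform draw among the two other codes
        shift = rng.integers(1, 3, size=out.shape)
        out[err] = (out[err] + shift[err]) % 3
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    return out


def simulate_dataset(config: SimConfig) -> SimTruth:
    """Full dataset: founders, trio offspring via simulated meioses, fully
    phased truth haplotypes, and observed genotypes after error/missingness."""
    rng = np.random.default_rng(config.seed)
    pedigree = build_pedigree(config, rng)
    marker_map = build_marker_map(config, rng)
    founder_ids = [i for i in pedigree.individuals() if i.startswith("F")]
    duo_ids = [i for i in pedigree.individuals() if i.startswith("D")]
    child_ids = [i for i in pedigree.individuals() if i.startswith("C")]
    founders, freqs = simulate_founder_haplotypes(
        config, len(founder_ids), rng=rng, marker_map=marker_map,
        sample_ids=founder_ids)
    n_var = founders.n_variants
    sample_ids = founder_ids + duo_ids + child_ids
    hapA = np.empty((n_var, len(sample_ids)), dtype=np.int8)
    hapB = np.empty_like(hapA)
    hapA[:, :len(founder_ids)] = founders.hapA
    hapB[:, :len(founder_ids)] = founders.hapB
    colof = {s: k for k, s in enumerate(sample_ids)}
    scale = {"male": config.male_scale, "female": config.female_scale,
             "unknown": 1.0}

    chrom_slices = {c: founders.chrom_slice(c) for c in founders.chromosomes()}
    co_log: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def meiosis(parent: str, child: str, target: np.ndarray) -> None:
        key = (parent, child)
        co_log[key] = {}
        p, col = colof[parent], colof[child]
        for c, sl in chrom_slices.items():
            pos, cm = marker_map.chrom_markers(c)
            gamete, co = simulate_gamete(
                hapA[sl, p], hapB[sl, p], pos, cm,
                scale[pedigree.sex_of(parent)], rng)
            target[sl, col] = gamete
            co_log[key][c] = co

    # duo offspring: one transmitted gamete, one haplotype from an
    # unobserved population parent
    for child in duo_ids:
        sire, dam = pedigree.parents_of(child)
        hidden = _draw_population_haps(config, 1, freqs, marker_map, rng)[:, 0]
        if sire is not None:
            meiosis(sire, child, hapA)
            hapB[:, colof[child]] = hidden
        else:
            meiosis(dam, child, hapB)
            hapA[:, colof[child]] = hidden

    for child in child_ids:
        sire, dam = pedigree.parents_of(child)
        meiosis(sire, child, hapA)
        meiosis(dam, child, hapB)

    truth = HaplotypeSet(marker_map.chroms, marker_map.positions, sample_ids,
                         hapA, hapB, np.ones(hapA.shape, dtype=bool))
    observed_calls = _apply_noise((hapA + hapB).astype(np.int8),
                                  config.genotype_error_rate,
                                  config.missing_rate, rng)
    observed = GenotypeMatrix(marker_map.chroms, marker_map.positions,
                              sample_ids, observed_calls)
    return SimTruth(config, pedigree, marker_map, freqs, truth, observed, co_log)


def corrupt_haplotypes(truth: HaplotypeSet, long_switch_rate_per_Mb: float = 0.0,
                       point_switch_rate_per_site: float = 0.0,
                       unphase_fraction: float = 0.0, seed: int = 0,
                       ) -> tuple[HaplotypeSet, pd.DataFrame]:
    """Controlled phasing-error injection, standing in for an imperfect
    population phaser.

    Long switches are a homogeneous Poisson process along each chromosome
    (rate per Mb over the marker span); downstream of each breakpoint the
    haplotype labels swap cumulatively, so a second breakpoint restores the
    original orientation. Point switches flip single sites independently.
    ``unphase_fraction`` of heterozygous sites lose their phase flag.
    Genotypes are unchanged. Returns the corrupted set and an event log with
    columns (individual, chrom, kind, position).
    """
    for name, v in (("long_switch_rate_per_Mb", long_switch_rate_per_Mb),
                    ("point_switch_rate_per_site", point_switch_rate_per_site),
                    ("unphase_fraction", unphase_fraction)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if not truth.phased.all():
        raise ValueError("corrupt_haplotypes requires a fully phased truth set")
    rng = np.random.default_rng(seed)
    out = truth.copy()
    events: list[tuple[str, str, str, int]] = []
    for c, sl in truth.iter_chromosomes():
        pos = truth.positions[sl]
        span_mb = (pos[-1] - pos[0]) / 1e6 if len(pos) > 1 else 0.0
        for j, ind in enumerate(truth.sample_ids):
            n_long = rng.poisson(long_switch_rate_per_Mb * span_mb)
            bp = np.sort(rng.uniform(pos[0], pos[-1], size=n_long)).astype(np.int64)
            swap = (np.searchsorted(bp, pos, side="left") % 2).astype(bool)
            flips = rng.random(len(pos)) < point_switch_rate_per_site
            swap ^= flips
            a = out.hapA[sl, j].copy()
            out.hapA[sl, j] = np.where(swap, out.hapB[sl, j], a)
            out.hapB[sl, j] = np.where(swap, a, out.hapB[sl, j])
            events.extend((ind, c, "long_switch", int(x)) for x in bp)
            events.extend((ind, c, "point_switch", int(pos[i]))
                          for i in np.flatnonzero(flips))
            if unphase_fraction > 0:
                het = np.flatnonzero(out.hapA[sl, j] != out.hapB[sl, j])
                n_up = int(round(unphase_fraction * len(het)))
                if n_up:
                    up = rng.choice(het, size=n_up, replace=False)
                    ph = out.phased[sl, j]
                    ph[up] = False
                    out.phased[sl, j] = ph
                    events.extend((ind, c, "unphase", int(pos[i])) for i in up)
    log = pd.DataFrame(events, columns=["individual", "chrom", "kind", "position"])
    return out, log


def inject_artifact_variants(sim: SimTruth, n_artifacts: int,
                             mode: Literal["iid_hwe", "excess_het"] = "iid_hwe",
                             seed: int = 0, freq: float = 0.3) -> SimTruth:
    """Append non-Mendelian artifact variants at random positions.

    ``iid_hwe``: genotypes drawn iid from Hardy-Weinberg proportions at
    ``freq``, ignoring the pedigree (so parent-offspring pairs show chance
    opposite homozygotes). ``excess_het``: every carrier is heterozygous
    (het probability 2*freq*(1-freq), otherwise hom-ref). Artifacts are
    flagged in ``artifact_flags`` so QC recall/precision is computable.
    """
    if n_artifacts < 0:
        raise ValueError("n_artifacts must be >= 0")
    if n_artifacts == 0:
        return sim
    rng = np.random.default_rng(seed)
    mm, th, obs = sim.marker_map, sim.truth_haps, sim.observed
    n_samples = th.n_samples
    chrom_names = list(dict.fromkeys(mm.chroms))
    existing = {(c, int(p)) for c, p in zip(mm.chroms, mm.positions)}
    new: list[tuple[str, int]] = []
    for _ in range(n_artifacts):
        for _try in range(100):
            c = chrom_names[rng.integers(len(chrom_names))]
            p = int(rng.integers(sim.config.chrom_bp_length))
            if (c, p) not in existing:
                existing.add((c, p))
                new.append((c, p))
                break
        else:
            raise RuntimeError("could not place artifact variant")

    if mode == "iid_hwe":
        u = rng.random((n_artifacts, n_samples))
        g = np.full((n_artifacts, n_samples), 1, dtype=np.int8)
        g[u < (1 - freq) ** 2] = 0
        g[u > 1 - freq ** 2] = 2
    elif mode == "excess_het":
        g = (rng.random((n_artifacts, n_samples)) < 2 * freq * (1 - freq)
             ).astype(np.int8)
    else:
        raise ValueError(f"unknown artifact mode {mode!r}")

    # merge the new rows into position-sorted per-chromosome order
    all_chroms = np.concatenate([mm.chroms, np.array([c for c, _ in new], dtype=object)])
    all_pos = np.concatenate([mm.positions, np.array([p for _, p in new], dtype=np.int64)])
    order = np.lexsort((all_pos, np.array(
        [chrom_names.index(c) for c in all_chroms])))
    n_old = len(mm.positions)

    def merged(old: np.ndarray, addition: np.ndarray) -> np.ndarray:
        return np.concatenate([old, addition])[order]

    new_cm = np.array([float(np.interp(p, mm.chrom_markers(c)[0].astype(float),
                                       mm.chrom_markers(c)[1])) for c, p in new])
    art_hapA = np.where(g == 2, 1, np.where(g == 1, 0, 0)).astype(np.int8)
    art_hapB = np.where(g >= 1, 1, 0).astype(np.int8)
    flags = merged(sim.artifact_flags, np.ones(n_artifacts, dtype=bool))
    truth = HaplotypeSet(merged(mm.chroms, np.array([c for c, _ in new], dtype=object)),
                         merged(mm.positions, np.array([p for _, p in new], dtype=np.int64)),
                         th.sample_ids,
                         merged(th.hapA, art_hapA), merged(th.hapB, art_hapB),
                         merged(th.phased, np.zeros((n_artifacts, n_samples), dtype=bool)))
    observed = GenotypeMatrix(truth.chroms, truth.positions, obs.sample_ids,
                              merged(obs.calls, g))
    new_map = MarkerMap(truth.chroms, truth.positions, merged(mm.cM, new_cm))
    new_freqs = merged(sim.freqs, np.full(n_artifacts, freq))
    return replace(sim, marker_map=new_map, freqs=new_freqs, truth_haps=truth,
                   observed=observed, artifact_flags=flags)


def inject_map_errors(sim: SimTruth, block_span_bp: int,
                      destination_offset_bp: int, seed: int = 0,
                      chrom: str | None = None, block_start_bp: int | None = None
                      ) -> SimTruth:
    """Relocate a contiguous marker block by an offset, emulating a
    misassembled segment.

    The arithmetic mimics a wrong assembly: the segment's coordinate range
    is excised from its true location and re-inserted ``offset`` bp away,
    sliding the intervening markers by the segment span, so all coordinates
    stay unique and ordered with the block displaced as a unit. Genotypes
    are untouched; the apparent genetic map interpolates cM at the wrong
    coordinates. The relocation is recorded in ``relocations``.
    """
    if destination_offset_bp == 0:
        return sim
    rng = np.random.default_rng(seed)
    mm = sim.marker_map
    chrom_names = list(dict.fromkeys(mm.chroms))
    L = sim.config.chrom_bp_length
    c = chrom if chrom is not None else chrom_names[rng.integers(len(chrom_names))]
    off = int(destination_offset_bp)
    if block_start_bp is not None:
        start = int(block_start_bp)
    else:
        lo = max(0, -off)
        hi = L - block_span_bp - max(0, off)
        if hi <= lo:
            raise ValueError("block and offset do not fit the chromosome")
        start = int(rng.integers(lo, hi))
    end = start + block_span_bp
    if not (0 <= start + off and end + off <= L):
        raise ValueError("relocated block falls outside the chromosome")

    sel = sim.truth_haps.chroms == c
    pos = sim.truth_haps.positions
    new_pos_all = pos.copy()
    block_global = sel & (pos >= start) & (pos < end)
    new_pos_all[block_global] += off
    if off > 0:
        between = sel & (pos >= end) & (pos < end + off)
        new_pos_all[between] -= block_span_bp
    else:
        between = sel & (pos >= start + off) & (pos < start)
        new_pos_all[between] += block_span_bp
    chrom_rank = np.array([chrom_names.index(cc) for cc in sim.truth_haps.chroms])
    order = np.lexsort((new_pos_all, chrom_rank))

    th = sim.truth_haps
    truth = HaplotypeSet(th.chroms[order], new_pos_all[order], th.sample_ids,
                         th.hapA[order], th.hapB[order], th.phased[order])
    observed = GenotypeMatrix(truth.chroms, truth.positions,
                              sim.observed.sample_ids, sim.observed.calls[order])
    # the apparent map believes the wrong coordinates
    moved = block_global | between
    new_cm = sim.marker_map.cM.copy()
    orig_pos, orig_cm = sim.marker_map.chrom_markers(c)
    new_cm[moved] = np.interp(new_pos_all[moved], orig_pos.astype(float),
                              orig_cm)
    new_map = MarkerMap(truth.chroms, truth.positions, new_cm[order])
    rec = {"chrom": c, "orig_start": int(start), "orig_end": int(end),
           "offset": off, "new_start": int(start + off),
           "new_end": int(end + off)}
    return replace(sim, marker_map=new_map, truth_haps=truth, observed=observed,
                   artifact_flags=sim.artifact_flags[order],
                   freqs=sim.freqs[order],
                   relocations=sim.relocations + [rec])


def simulate_depth_track(individuals: Sequence[str], chrom: str,
                         chrom_length: int, window_bp: int = 10_000,
                         mean_depth: float = 25.8, sigma: float = 0.2,
                         high_region: tuple[int, int, float] | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Per-individual windowed depths, lognormal around ``mean_depth``
    (default the study-scale 25.8x). ``high_region=(start, end, factor)``
    multiplies depth inside that interval — a stand-in for a collapsed
    repeat. Returns BED+value columns (chrom, start, end, individual, depth)."""
    rng = np.random.default_rng(seed)
    starts = np.arange(0, chrom_length, window_bp)
    rows = []
    for ind in individuals:
        depth = mean_depth * rng.lognormal(-sigma ** 2 / 2, sigma, size=len(starts))
        if high_region is not None:
            s, e, f = high_region
            depth[(starts + window_bp > s) & (starts < e)] *= f
        for st, d in zip(starts, depth):
            rows.append((chrom, int(st), int(min(st + window_bp, chrom_length)),
                         ind, float(d)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "individual",
                                       "depth"])
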