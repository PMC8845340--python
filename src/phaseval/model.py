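"""Core in-memory containers for pedigree phasing analyses.

Conventions used throughout the package:

* genotype codes count alternate alleles: ``0``, ``1``, ``2``; missing is ``-1``;
* haplotype alleles are ``0``/``1``; missing is ``-1``;
* all internal coordinates are 0-based, intervals half-open ``[start, end)``.
  VCF/BED/map readers and writers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MISSING = -1

Sex = str  # "male" | "female" | "unknown"


def _check_axes(chroms: np.ndarray, positions: np.ndarray, sample_ids: Sequence[str]) -> None:
    if len(chroms) != len(positions):
        raise ValueError("chroms and positions must have equal length")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_ids must be unique")
    # chromosome blocks contiguous, positions strictly increasing within each
    seen: set[str] = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            seen.add(c)
            prev = c
    for c in seen:
        pos = positions[chroms == c]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {c!r}")


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for variants x samples.

    ``calls[i, j]`` is the alternate-allele count of sample ``j`` at variant
    ``i`` (-1 for missing). Variants are grouped by chromosome and sorted by
    position within each chromosome.
    """

    chroms: np.ndarray            # (n_var,) str
    positions: np.ndarray         # (n_var,) int64, 0-based
    sample_ids: list[str]
    calls: np.ndarray             # (n_var, n_samples) int8

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        _check_axes(self.chroms, self.positions, self.sample_ids)
        if self.calls.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError("calls shape does not match axes")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chroms:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def iter_chromosomes(self) -> Iterator[tuple[str, slice]]:
        for c in self.chromosomes():
            yield c, self.chrom_slice(c)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(self.chroms[keep], self.positions[keep],
                              self.sample_ids, self.calls[keep])


@dataclass
class HaplotypeSet:
    """Per-sample pairs of haplotypes on the same variant axes as a
    :class:`GenotypeMatrix`.

    Where ``phased`` is False the hapA/hapB order carries no meaning; where it
    is True, ``hapA + hapB`` equals the genotype. ``hapA`` is the paternal
    haplotype whenever the source established parental origin (trio phasing,
    the simulator); population phasers assign arbitrary but consistent sides.
    """

    chroms: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    hapA: np.ndarray              # (n_var, n_samples) int8 in {-1, 0, 1}
    hapB: np.ndarray
    phased: np.ndarray            # (n_var, n_samples) bool

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        self.hapA = np.asarray(self.hapA, dtype=np.int8)
        self.hapB = np.asarray(self.hapB, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        _check_axes(self.chroms, self.positions, self.sample_ids)
        shape = (len(self.positions), len(self.sample_ids))
        for name in ("hapA", "hapB", "phased"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match axes")
        for h in (self.hapA, self.hapB):
            if np.any(~np.isin(h, (MISSING, 0, 1))):
                raise ValueError("haplotype alleles must be in {-1, 0, 1}")
        # a phased site must have both alleles known
        if np.any(self.phased & ((self.hapA == MISSING) | (self.hapB == MISSING))):
            raise ValueError("phased sites must carry two non-missing alleles")

    n_variants = GenotypeMatrix.n_variants
    n_samples = GenotypeMatrix.n_samples
    chromosomes = GenotypeMatrix.chromosomes
    chrom_slice = GenotypeMatrix.chrom_slice
    iter_chromosomes = GenotypeMatrix.iter_chromosomes
    sample_index = GenotypeMatrix.sample_index

    def genotypes(self) -> GenotypeMatrix:
        """Collapse to unphased genotype codes (missing where either allele is)."""
        calls = (self.hapA + self.hapB).astype(np.int8)
        calls[(self.hapA == MISSING) | (self.hapB == MISSING)] = MISSING
        return GenotypeMatrix(self.chroms, self.positions, self.sample_ids, calls)

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(self.chroms.copy(), self.positions.copy(),
                            list(self.sample_ids), self.hapA.copy(),
                            self.hapB.copy(), self.phased.copy())


@dataclass(frozen=True)
class PedigreeRecord:
    individual: str
    sire: str | None
    dam: str | None
    sex: Sex = "unknown"


class Pedigree:
    """Individual -> (sire, dam, sex) with derived trio/duo structure."""

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.individual in self.records:
                raise ValueError(f"duplicate pedigree record for {r.individual!r}")
            self.records[r.individual] = r
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(ind: str, stack: list[str]) -> None:
            if ind not in self.records or state.get(ind) == 1:
                return
            if state.get(ind) == 0:
                raise ValueError(f"pedigree cycle involving {ind!r}")
            state[ind] = 0
            stack.append(ind)
            r = self.records[ind]
            for parent in (r.sire, r.dam):
                if parent is not None:
                    visit(parent, stack)
            stack.pop()
            state[ind] = 1

        for ind in self.records:
            visit(ind, [])

    def __contains__(self, individual: str) -> bool:
        return individual in self.records

    def __len__(self) -> int:
        return len(self.records)

    def individuals(self) -> list[str]:
        return list(self.records)

    def sex_of(self, individual: str) -> Sex:
        r = self.records.get(individual)
        return r.sex if r is not None else "unknown"

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        r = self.records.get(individual)
        if r is None:
            return (None, None)
        return (r.sire, r.dam)

    def find_trios(self, sample_ids: Sequence[str]) -> list[tuple[str, str, str]]:
        """Offspring with BOTH parents among ``sample_ids``: (child, sire, dam)."""
        present = set(sample_ids)
        trios = []
        for r in self.records.values():
            if r.individual in present and r.sire in present and r.dam in present:
                trios.append((r.individual, r.sire, r.dam))
        return trios

    def find_duos(self, sample_ids: Sequence[str]) -> list[tuple[str, str]]:
        """Offspring with EXACTLY one parent among ``sample_ids``: (child, parent)."""
        present = set(sample_ids)
        duos = []
        for r in self.records.values():
            if r.individual not in present:
                continue
            sire_in = r.sire in present
            dam_in = r.dam in present
            if sire_in != dam_in:
                duos.append((r.individual, r.sire if sire_in else r.dam))
        return duos

    def parent_offspring_pairs(self, sample_ids: Sequence[str]) -> list[tuple[str, str]]:
        """All genotyped (parent, offspring) pairs — two per trio, one per duo."""
        present = set(sample_ids)
        pairs = []
        for r in self.records.values():
            if r.individual not in present:
                continue
            for parent in (r.sire, r.dam):
                if parent in present:
                    pairs.append((parent, r.individual))
        return pairs


@dataclass
class MarkerMap:
    """Genetic map: per marker chromosome, bp position (0-based) and cM."""

    chroms: np.ndarray
    positions: np.ndarray         # int64, 0-based
    cM: np.ndarray                # float64

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cM = np.asarray(self.cM, dtype=float)
        _check_axes(self.chroms, self.positions, [])
        for c in set(self.chroms):
            cm = self.cM[self.chroms == c]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not non-decreasing on chromosome {c!r}")

    def chrom_markers(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.chroms == chrom
        if not sel.any():
            raise KeyError(f"chromosome {chrom!r} not in map")
        return self.positions[sel], self.cM[sel]

    def chrom_cM_length(self, chrom: str) -> float:
        _, cm = self.chrom_markers(chrom)
        return float(cm[-1] - cm[0])

    def cM_to_bp(self, chrom: str, cm_values: np.ndarray) -> np.ndarray:
        """Linear interpolation from the cM scale to bp (ties broken left)."""
        pos, cm = self.chrom_markers(chrom)
        return np.interp(cm_values, cm, pos.astype(float)).astype(np.int64)

    def bp_to_cM(self, chrom: str, bp_values: np.ndarray) -> np.ndarray:
        pos, cm = self.chrom_markers(chrom)
        return np.interp(bp_values, pos.astype(float), cm)


def merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        if e < s:
            raise ValueError(f"interval end before start: ({c}, {s}, {e})")
        if e > s:
            by_chrom.setdefault(c, []).append((int(s), int(e)))
    merged: list[tuple[str, int, int]] = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((c, cur_s, cur_e))
    return merged


@dataclass
class RegionMask:
    """A set of genomic intervals (0-based half-open), stored merged+sorted."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def union(self, *others: "RegionMask") -> "RegionMask":
        ivs = list(self.intervals)
        for o in others:
            ivs.extend(o.intervals)
        return RegionMask(ivs)

    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: is each (chrom, pos) point inside any interval."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        for c in set(chroms):
            ivs = [(s, e) for cc, s, e in self.intervals if cc == c]
            if not ivs:
                continue
            sel = chroms == c
            pos = positions[sel]
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            idx = np.searchsorted(starts, pos, side="right") - 1
            hit = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            res = np.zeros(pos.shape, dtype=bool)
            res[hit] = True
            out[sel] = res
        return out

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionMask) and self.intervals == other.intervals
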