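"""Gold-standard haplotypes from trios/duos by Mendelian segregation rules.

Rules are applied site-wise only — no linkage or LD inference — so that the
resulting haplotypes are exact in the absence of genotyping errors. Sites
that Mendelian logic cannot resolve (e.g. both parents heterozygous) stay
unphased; conflicting configurations are flagged, never phased.

The single-site rule lives in :func:`phase_trio_site`; everything else is a
vectorised application of its 4x4x4 lookup table (codes 0/1/2/missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .model import MISSING, GenotypeMatrix, HaplotypeSet, Pedigree

VALID_CODES = (MISSING, 0, 1, 2)

InconsistencyKind = Literal["opposite_homozygote_pair", "impossible_trio"]


@dataclass(frozen=True)
class InconsistencyRecord:
    variant_index: int
    offspring: str
    parents: tuple[str, ...]
    kind: InconsistencyKind


def _transmissible(gt: int) -> set[int]:
    """Alleles a parent with this genotype can transmit (missing -> both)."""
    if gt == 0:
        return {0}
    if gt == 2:
        return {1}
    return {0, 1}   # het or missing


def phase_trio_site(child_gt: int, sire_gt: int, dam_gt: int
                    ) -> tuple[int | None, int | None, bool]:
    """Resolve one site of one trio (duo: code the absent parent missing).

    Returns (paternal allele, maternal allele, inconsistency flag). Alleles
    are None when unresolved; a flagged site is never assigned. Assignment
    happens iff exactly one (paternal, maternal) combination is compatible
    with the three genotypes; with no compatible combination the site is a
    Mendelian inconsistency.
    """
    for gt in (child_gt, sire_gt, dam_gt):
        if gt not in VALID_CODES:
            raise ValueError(f"invalid genotype code {gt!r}")
    if child_gt == MISSING:
        return None, None, False
    feasible = [(p, m) for p in _transmissible(sire_gt)
                for m in _transmissible(dam_gt) if p + m == child_gt]
    if not feasible:
        return None, None, True
    if len(feasible) == 1:
        p, m = feasible[0]
        return p, m, False
    return None, None, False


def _is_opposite_hom(a: int, b: int) -> bool:
    return (a == 0 and b == 2) or (a == 2 and b == 0)


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorise phase_trio_site: tables indexed by (child, sire, dam) with
    missing mapped to index 3. PAT/MAT hold the assigned allele or -1;
    INC the inconsistency flag."""
    codes = [0, 1, 2, MISSING]
    pat = np.full((4, 4, 4), -1, dtype=np.int8)
    mat = np.full((4, 4, 4), -1, dtype=np.int8)
    inc = np.zeros((4, 4, 4), dtype=bool)
    for ic, c in enumerate(codes):
        for is_, s in enumerate(codes):
            for id_, d in enumerate(codes):
                p, m, bad = phase_trio_site(c, s, d)
                if p is not None:
                    pat[ic, is_, id_] = p
                    mat[ic, is_, id_] = m
                inc[ic, is_, id_] = bad
    return pat, mat, inc


_PAT, _MAT, _INC = _build_tables()


def _idx(codes: np.ndarray) -> np.ndarray:
    """Map genotype codes to table indices (missing -> 3)."""
    return np.where(codes == MISSING, 3, codes).astype(np.intp)


def phase_pedigree(genotypes: GenotypeMatrix, pedigree: Pedigree) -> HaplotypeSet:
    """Phase every offspring with at least one genotyped parent, site-wise.

    hapA is paternal, hapB maternal. Unresolved and inconsistent sites are
    left unphased; individuals without genotyped parents are untouched
    (fully unphased).
    """
    trios = pedigree.find_trios(genotypes.sample_ids)
    duos = pedigree.find_duos(genotypes.sample_ids)
    if not trios and not duos:
        raise ValueError("no trios or duos found among genotyped samples")

    calls = genotypes.calls
    n_var, n_s = calls.shape
    # default: unphased placeholders consistent with the genotype
    hapA = np.where(calls == 2, 1, np.where(calls == MISSING, MISSING, 0)
                    ).astype(np.int8)
    hapB = np.where(calls >= 1, 1, np.where(calls == MISSING, MISSING, 0)
                    ).astype(np.int8)
    phased = np.zeros((n_var, n_s), dtype=bool)

    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    families = [(c, s, d) for c, s, d in trios]
    for child, parent in duos:
        sire, dam = pedigree.parents_of(child)
        if parent == sire:
            families.append((child, parent, None))
        else:
            families.append((child, None, parent))

    missing_col = np.full(n_var, 3, dtype=np.intp)
    for child, sire, dam in families:
        ci = _idx(calls[:, col[child]])
        si = _idx(calls[:, col[sire]]) if sire is not None else missing_col
        di = _idx(calls[:, col[dam]]) if dam is not None else missing_col
        p = _PAT[ci, si, di]
        m = _MAT[ci, si, di]
        ok = p >= 0
        j = col[child]
        hapA[ok, j] = p[ok]
        hapB[ok, j] = m[ok]
        phased[ok, j] = True
    return HaplotypeSet(genotypes.chroms, genotypes.positions,
                        genotypes.sample_ids, hapA, hapB, phased)


def find_mendelian_inconsistencies(genotypes: GenotypeMatrix,
                                   pedigree: Pedigree
                                   ) -> list[InconsistencyRecord]:
    """List every opposite-homozygote parent-offspring pair and every
    impossible trio configuration (trio conflicts not explained by an
    opposite-homozygote pair)."""
    records: list[InconsistencyRecord] = []
    calls = genotypes.calls
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}

    for parent, child in pedigree.parent_offspring_pairs(genotypes.sample_ids):
        gp, gc = calls[:, col[parent]], calls[:, col[child]]
        opp = ((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))
        for i in np.flatnonzero(opp):
            records.append(InconsistencyRecord(int(i), child, (parent,),
                                               "opposite_homozygote_pair"))

    for child, sire, dam in pedigree.find_trios(genotypes.sample_ids):
        gc = calls[:, col[child]]
        gs = calls[:, col[sire]]
        gd = calls[:, col[dam]]
        bad = _INC[_idx(gc), _idx(gs), _idx(gd)]
        # trio conflicts already captured as opposite-homozygote pairs are
        # reported under that kind only
        opp = (((gs == 0) & (gc == 2)) | ((gs == 2) & (gc == 0))
               | ((gd == 0) & (gc == 2)) | ((gd == 2) & (gc == 0)))
        for i in np.flatnonzero(bad & ~opp):
            records.append(InconsistencyRecord(int(i), child, (sire, dam),
                                               "impossible_trio"))
    records.sort(key=lambda r: r.variant_index)
    return records


def count_inconsistencies_per_variant(genotypes: GenotypeMatrix,
                                      pedigree: Pedigree) -> np.ndarray:
    """Per-variant total of opposite-homozygote pairs plus impossible trios
    (the quantity the 'at most one inconsistency' filter thresholds)."""
    calls = genotypes.calls
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    counts = np.zeros(genotypes.n_variants, dtype=np.int64)
    for parent, child in pedigree.parent_offspring_pairs(genotypes.sample_ids):
        gp, gc = calls[:, col[parent]], calls[:, col[child]]
        counts += ((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))
    for child, sire, dam in pedigree.find_trios(genotypes.sample_ids):
        gc, gs, gd = (calls[:, col[x]] for x in (child, sire, dam))
        bad = _INC[_idx(gc), _idx(gs), _idx(gd)]
        opp = (((gs == 0) & (gc == 2)) | ((gs == 2) & (gc == 0))
               | ((gd == 0) & (gc == 2)) | ((gd == 2) & (gc == 0)))
        counts += bad & ~opp
    return counts


def mask_incompatible_genotypes(genotypes: GenotypeMatrix,
                                records: Sequence[InconsistencyRecord]
                                ) -> GenotypeMatrix:
    """Set every member of each conflicting family to missing at the
    conflicting site (the true error source is unknown, so both sides of a
    pair are removed)."""
    calls = genotypes.calls.copy()
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    for r in records:
        calls[r.variant_index, col[r.offspring]] = MISSING
        for parent in r.parents:
            calls[r.variant_index, col[parent]] = MISSING
    return GenotypeMatrix(genotypes.chroms, genotypes.positions,
                          genotypes.sample_ids, calls)
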