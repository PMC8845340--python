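"""Crossover identification in parent-offspring pairs (proband-gamete).

At sites where the transmitted allele from a phased parent can be deduced
(child homozygous, or child heterozygous with the other parent homozygous)
and the parent is heterozygous and phased, the parental origin of the
gamete is known. Runs of constant origin separated by origin flips mark
crossovers; isolated short runs (below ``min_support`` sites) are masked as
noise — single genotyping errors otherwise generate spurious double
crossovers. Genome-wide crossover counts per meiosis, compared with the
genetic-map expectation (~24.5 genome-wide, 26 in males and 23 in females
for cattle), are the data-quality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, HaplotypeSet, Pedigree

__all__ = ["OriginVector", "CrossoverCall", "assign_parental_origin",
           "call_crossovers", "analyze_meioses", "co_summary"]


@dataclass
class OriginVector:
    """Transmitted parental haplotype (1 or 2) per deducible informative
    site of one meiosis on one chromosome."""

    parent: str
    child: str
    chrom: str
    positions: np.ndarray         # bp of sites with known origin
    origins: np.ndarray           # int8 in {1, 2}
    n_conflicts: int = 0          # transmitted allele on neither parent hap

    def restrict(self, keep_positions: np.ndarray) -> "OriginVector":
        sel = np.isin(self.positions, keep_positions)
        return OriginVector(self.parent, self.child, self.chrom,
                            self.positions[sel], self.origins[sel],
                            self.n_conflicts)


@dataclass(frozen=True)
class CrossoverCall:
    parent: str
    child: str
    chrom: str
    start: int                    # bp of last supporting site before
    end: int                      # bp of first supporting site after


def assign_parental_origin(parent_hapA: np.ndarray, parent_hapB: np.ndarray,
                           parent_phased: np.ndarray, child_gt: np.ndarray,
                           other_parent_gt: np.ndarray, positions: np.ndarray,
                           parent: str = "parent", child: str = "child",
                           chrom: str = "1") -> OriginVector:
    """Deduce which parental haplotype was transmitted at each site.

    The transmitted allele from the focal parent is known when the child is
    homozygous (the allele itself) or heterozygous with the other parent
    homozygous (child sum minus the other parent's forced allele). Where the
    focal parent is phased-heterozygous, the origin is the haplotype index
    carrying that allele. Sites where the transmitted allele matches neither
    parental haplotype are conflicts: excluded and counted.
    """
    transmitted = np.full(len(positions), MISSING, dtype=np.int8)
    transmitted[child_gt == 0] = 0
    transmitted[child_gt == 2] = 1
    het = child_gt == 1
    transmitted[het & (other_parent_gt == 0)] = 1
    transmitted[het & (other_parent_gt == 2)] = 0

    known = transmitted != MISSING
    conflict = known & (
        ((parent_hapA == parent_hapB)
         & (parent_hapA != MISSING) & (parent_hapA != transmitted)))
    phased_het = parent_phased & (parent_hapA != parent_hapB) \
        & (parent_hapA != MISSING) & (parent_hapB != MISSING)
    usable = known & phased_het & ~conflict
    origins = np.where(parent_hapA == transmitted, 1, 2).astype(np.int8)
    return OriginVector(parent, child, chrom, positions[usable],
                        origins[usable], int(conflict.sum()))


def call_crossovers(origin: OriginVector, min_support: int = 3
                    ) -> list[CrossoverCall]:
    """Run-length encode the origin vector, mask runs shorter than
    ``min_support`` sites as noise, and emit one call per boundary between
    surviving runs of different origin, localized between the last
    supporting site on the left and the first on the right."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    o, pos = origin.origins, origin.positions
    if len(o) == 0:
        return []
    change = np.flatnonzero(np.diff(o)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(o)]])
    runs = [(o[s], s, e) for s, e in zip(starts, ends) if e - s >= min_support]
    calls: list[CrossoverCall] = []
    for (o1, _, e1), (o2, s2, _) in zip(runs, runs[1:]):
        if o1 != o2:
            calls.append(CrossoverCall(origin.parent, origin.child,
                                       origin.chrom, int(pos[e1 - 1]),
                                       int(pos[s2])))
    return calls


def analyze_meioses(parent_haps: HaplotypeSet, genotypes: GenotypeMatrix,
                    pedigree: Pedigree, min_support: int = 3,
                    ) -> tuple[list[CrossoverCall], list[OriginVector]]:
    """Origin vectors and crossover calls for every genotyped
    parent-offspring pair whose parent has phased sites.

    Parent haplotypes may come from trio phasing, simulation truth or any
    phased VCF; the deduction is agnostic to their source.
    """
    col_h = {s: j for j, s in enumerate(parent_haps.sample_ids)}
    col_g = {s: j for j, s in enumerate(genotypes.sample_ids)}
    calls: list[CrossoverCall] = []
    origins: list[OriginVector] = []
    for parent, child in pedigree.parent_offspring_pairs(genotypes.sample_ids):
        if parent not in col_h:
            continue
        jp, jc = col_h[parent], col_g[child]
        if not parent_haps.phased[:, jp].any():
            continue
        sire, dam = pedigree.parents_of(child)
        other = dam if parent == sire else sire
        for c, sl in genotypes.iter_chromosomes():
            other_gt = (genotypes.calls[sl, col_g[other]]
                        if other in col_g else
                        np.full(sl.stop - sl.start, MISSING, dtype=np.int8))
            ov = assign_parental_origin(
                parent_haps.hapA[sl, jp], parent_haps.hapB[sl, jp],
                parent_haps.phased[sl, jp], genotypes.calls[sl, jc],
                other_gt, genotypes.positions[sl], parent, child, c)
            origins.append(ov)
            calls.extend(call_crossovers(ov, min_support))
    return calls, origins


def co_summary(calls: Sequence[CrossoverCall], pedigree: Pedigree,
               expectation: float | None = None,
               meioses: Sequence[tuple[str, str]] | None = None,
               ) -> tuple[pd.DataFrame, dict]:
    """Per-meiosis genome-wide crossover counts and cohort means.

    ``meioses`` lists the (parent, child) pairs that were analyzed, so that
    meioses with zero detected crossovers enter the means (they are omitted
    if only ``calls`` is given). ``expectation`` is the expected genome-wide
    count per meiosis from a trusted map (Morgans of map length); the
    inflation ratio mean/expectation is the headline data-quality
    diagnostic.
    """
    counts: dict[tuple[str, str], int] = {}
    if meioses is not None:
        counts = {tuple(m): 0 for m in meioses}
    for c in calls:
        counts[(c.parent, c.child)] = counts.get((c.parent, c.child), 0) + 1
    rows = [{"parent": p, "child": ch, "parent_sex": pedigree.sex_of(p),
             "n_co": n} for (p, ch), n in sorted(counts.items())]
    df = pd.DataFrame(rows, columns=["parent", "child", "parent_sex", "n_co"])
    summary = {
        "n_meioses": len(df),
        "mean_co": float(df["n_co"].mean()) if len(df) else 0.0,
        "mean_co_male": float(df.loc[df.parent_sex == "male", "n_co"].mean())
        if (df.parent_sex == "male").any() else 0.0,
        "mean_co_female": float(df.loc[df.parent_sex == "female", "n_co"].mean())
        if (df.parent_sex == "female").any() else 0.0,
    }
    if expectation is not None and expectation > 0:
        summary["expected_co"] = float(expectation)
        summary["inflation_ratio"] = summary["mean_co"] / expectation
    return df, summary
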