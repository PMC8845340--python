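"""Readers and writers for the standard formats: VCF (GT only), PLINK FAM,
genetic-map text, and BED region masks.

Only biallelic SNPs enter the data model; other records are skipped and
counted. VCF positions are 1-based and converted to the package's 0-based
internal convention on read (and back on write).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap,
                    Pedigree, PedigreeRecord, RegionMask)

log = logging.getLogger(__name__)

_SNP_ALLELES = {"A", "C", "G", "T"}


def _scan_vcf(path: str | Path):
    """Yield (variant, chrom, pos0) for biallelic SNP records; count the rest."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    genos: list[np.ndarray] = []
    skipped = 0
    last: dict[str, int] = {}
    for v in vcf:
        alts = v.ALT
        if (len(alts) != 1 or v.REF not in _SNP_ALLELES
                or alts[0] not in _SNP_ALLELES):
            skipped += 1
            continue
        pos0 = v.POS - 1
        if last.get(v.CHROM) == pos0:
            raise ValueError(
                f"duplicate position {v.CHROM}:{v.POS} in {path}")
        last[v.CHROM] = pos0
        chroms.append(v.CHROM)
        positions.append(pos0)
        genos.append(np.array(v.genotypes, dtype=object))
    if skipped:
        log.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    return samples, chroms, positions, genos


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into genotype codes (alternate-allele counts)."""
    samples, chroms, positions, genos = _scan_vcf(path)
    n_var, n_s = len(positions), len(samples)
    calls = np.full((n_var, n_s), MISSING, dtype=np.int8)
    for i, g in enumerate(genos):
        for j in range(n_s):
            a0, a1 = g[j][0], g[j][1]
            if a0 >= 0 and a1 >= 0:
                calls[i, j] = a0 + a1
    return GenotypeMatrix(np.array(chroms, dtype=object),
                          np.array(positions, dtype=np.int64), samples, calls)


def read_haplotypes(path: str | Path) -> HaplotypeSet:
    """Read a VCF into haplotypes; ``|`` marks phase, hapA is the left allele.

    A site is phased iff the separator is ``|`` and both alleles are
    non-missing: a half-known phase is unusable by the metrics.
    """
    samples, chroms, positions, genos = _scan_vcf(path)
    n_var, n_s = len(positions), len(samples)
    hapA = np.full((n_var, n_s), MISSING, dtype=np.int8)
    hapB = np.full((n_var, n_s), MISSING, dtype=np.int8)
    phased = np.zeros((n_var, n_s), dtype=bool)
    for i, g in enumerate(genos):
        for j in range(n_s):
            a0, a1, ph = g[j][0], g[j][1], bool(g[j][2])
            if a0 >= 0:
                hapA[i, j] = a0
            if a1 >= 0:
                hapB[i, j] = a1
            phased[i, j] = ph and a0 >= 0 and a1 >= 0
    return HaplotypeSet(np.array(chroms, dtype=object),
                        np.array(positions, dtype=np.int64), samples,
                        hapA, hapB, phased)


_VCF_HEADER = "##fileformat=VCFv4.2\n"


def _vcf_lines(chroms, positions, sample_ids, gt_strings):
    contigs: dict[str, int] = {}
    for c, p in zip(chroms, positions):
        contigs[c] = max(contigs.get(c, 0), int(p) + 1)
    yield _VCF_HEADER
    for c, ln in contigs.items():
        yield f"##contig=<ID={c},length={ln + 1}>\n"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    yield ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           + "\t".join(sample_ids) + "\n")
    for i, (c, p) in enumerate(zip(chroms, positions)):
        yield (f"{c}\t{int(p) + 1}\t.\tA\tC\t.\tPASS\t.\tGT\t"
               + "\t".join(gt_strings[i]) + "\n")


def _allele_str(a: int) -> str:
    return "." if a == MISSING else str(int(a))


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write genotype codes as an unphased GT-only VCF (REF=A, ALT=C)."""
    gt_map = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    gt = [[gt_map[int(x)] for x in row] for row in gm.calls]
    with open(path, "w") as fh:
        fh.writelines(_vcf_lines(gm.chroms, gm.positions, gm.sample_ids, gt))


def write_haplotypes(hs: HaplotypeSet, path: str | Path) -> None:
    """Write a HaplotypeSet as a GT-only VCF; phased sites use ``|``."""
    gt: list[list[str]] = []
    for i in range(hs.n_variants):
        row = []
        for j in range(hs.n_samples):
            sep = "|" if hs.phased[i, j] else "/"
            row.append(_allele_str(hs.hapA[i, j]) + sep + _allele_str(hs.hapB[i, j]))
        gt.append(row)
    with open(path, "w") as fh:
        fh.writelines(_vcf_lines(hs.chroms, hs.positions, hs.sample_ids, gt))


_SEX_CODE = {"1": "male", "2": "female"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PLINK FAM (FID IID SIRE DAM SEX PHENO); 0 = unknown."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     names=["fid", "iid", "sire", "dam", "sex", "pheno"])
    records = []
    ids = set(df["iid"])
    for row in df.itertuples(index=False):
        sire = None if row.sire in ("0", None) else row.sire
        dam = None if row.dam in ("0", None) else row.dam
        for parent in (sire, dam):
            if parent is not None and parent not in ids:
                log.warning("parent %s of %s has no pedigree record", parent, row.iid)
        records.append(PedigreeRecord(row.iid, sire, dam,
                                      _SEX_CODE.get(row.sex, "unknown")))
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for r in ped.records.values():
            fh.write(f"FAM\t{r.individual}\t{r.sire or 0}\t{r.dam or 0}\t"
                     f"{sex_code[r.sex]}\t-9\n")


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a 4-column genetic map: chrom, marker id, cM, bp (1-based)."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "cM", "bp"],
                     dtype={"chrom": str, "id": str, "cM": float, "bp": np.int64})
    return MarkerMap(df["chrom"].to_numpy(dtype=object),
                     df["bp"].to_numpy() - 1, df["cM"].to_numpy())


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (c, p, cm) in enumerate(zip(mm.chroms, mm.positions, mm.cM)):
            fh.write(f"{c}\tm{i}\t{cm:.8g}\t{int(p) + 1}\n")


def read_region_mask(path: str | Path) -> RegionMask:
    """Read a BED file (0-based half-open) into a RegionMask."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return RegionMask([(r.chrom, int(r.start), int(r.end))
                       for r in df.itertuples(index=False)])


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in mask.intervals:
            fh.write(f"{c}\t{s}\t{e}\n")


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read per-individual windowed depth as BED+value: chrom, start, end,
    individual, mean depth."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "individual", "depth"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "individual": str, "depth": float})
    if df.empty:
        raise ValueError(f"empty depth track: {path}")
    return df


def write_depth_track(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
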