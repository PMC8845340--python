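"""Genetic-rule variant filters producing the "true Mendelian variants" panel.

A variant is kept when it behaves like a real segregating SNP in the
pedigree: genotype frequencies close to Hardy-Weinberg proportions
(chi-square, keep p > 0.05), offspring of heterozygous parents segregating
1:2:1 or 1:1 as expected (chi-square, keep p > 0.05), at most one Mendelian
inconsistency over the whole pedigree, enough informativeness that a total
absence of inconsistencies could not plausibly arise by chance
(no-inconsistency probability < 1e-12 under an independent-pairs
Hardy-Weinberg model), minor allele frequency >= 0.01 and missing rate
<= 5%. After filtering, remaining opposite-homozygote genotypes are masked
and missingness/monomorphism re-checked ("final editions").

All test statistics are computed on the same input snapshot, before any
masking, so individual filters commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mendel import count_inconsistencies_per_variant, \
    find_mendelian_inconsistencies, mask_incompatible_genotypes
from .model import MISSING, GenotypeMatrix, Pedigree

CHANCE_PROB_FORMULA = ("P = (1 - 2*(1-p)^2 * p^2)^n_pairs; keep iff P < "
                       "threshold (HWE genotypes, independent pairs)")


def hwe_test(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions on
    genotype counts (hom-ref, het, hom-alt). Monomorphic input returns
    (0, 1) by convention."""
    chi2, p = hwe_test_many(np.array([[n0, n1, n2]]))
    return float(chi2[0]), float(p[0])


def hwe_test_many(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`hwe_test` over an (n, 3) array of genotype counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    if np.any(n <= 0):
        raise ValueError("each variant needs at least one genotyped individual")
    p_hat = (2 * counts[:, 2] + counts[:, 1]) / (2 * n)
    exp = np.column_stack([n * (1 - p_hat) ** 2,
                           2 * n * p_hat * (1 - p_hat),
                           n * p_hat ** 2])
    poly = (p_hat > 0) & (p_hat < 1)
    chi2 = np.zeros(len(n))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - exp) ** 2 / exp
    chi2[poly] = np.nansum(terms[poly], axis=1)
    p = np.where(poly, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def _genotype_counts(calls: np.ndarray) -> np.ndarray:
    return np.stack([(calls == g).sum(axis=1) for g in (0, 1, 2)], axis=1)


def segregation_test_all(genotypes: GenotypeMatrix, pedigree: Pedigree
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offspring segregation-distortion chi-square, per variant.

    Trio offspring are pooled by informative mating type: het x het expects
    1:2:1 over {0,1,2} (2 df); het x hom-ref expects 1:1 over {0,1} (1 df);
    het x hom-alt expects 1:1 over {1,2} (1 df). Component chi-squares and
    dfs are summed. Offspring genotypes impossible under the mating type
    (Mendelian conflicts, handled elsewhere) and missing genotypes are
    excluded. Variants with no informative matings get p = 1 and df = 0.
    Returns (chi2, df, p) arrays.
    """
    calls = genotypes.calls
    n_var = genotypes.n_variants
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    hh = np.zeros((n_var, 3))     # het x het offspring counts
    hr = np.zeros((n_var, 2))     # het x hom-ref: offspring in {0, 1}
    ha = np.zeros((n_var, 2))     # het x hom-alt: offspring in {1, 2}
    for child, sire, dam in pedigree.find_trios(genotypes.sample_ids):
        gc, gs, gd = (calls[:, col[x]] for x in (child, sire, dam))
        both_het = (gs == 1) & (gd == 1)
        for g in (0, 1, 2):
            hh[:, g] += both_het & (gc == g)
        het_ref = ((gs == 1) & (gd == 0)) | ((gs == 0) & (gd == 1))
        het_alt = ((gs == 1) & (gd == 2)) | ((gs == 2) & (gd == 1))
        for g, k in ((0, 0), (1, 1)):
            hr[:, k] += het_ref & (gc == g)
        for g, k in ((1, 0), (2, 1)):
            ha[:, k] += het_alt & (gc == g)

    chi2 = np.zeros(n_var)
    df = np.zeros(n_var, dtype=np.int64)
    n_hh = hh.sum(axis=1)
    use = n_hh > 0
    exp = np.outer(n_hh, [0.25, 0.5, 0.25])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 += np.where(use, np.nansum((hh - exp) ** 2 / exp, axis=1), 0.0)
    df += np.where(use, 2, 0)
    for comp in (hr, ha):
        n_c = comp.sum(axis=1)
        use = n_c > 0
        exp = np.outer(n_c, [0.5, 0.5])
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 += np.where(use, np.nansum((comp - exp) ** 2 / exp, axis=1), 0.0)
        df += np.where(use, 1, 0)
    p = np.where(df > 0, stats.chi2.sf(chi2, df=np.maximum(df, 1)), 1.0)
    return chi2, df, p


def offspring_segregation_test(genotypes: GenotypeMatrix, pedigree: Pedigree,
                               variant_index: int) -> tuple[float, int, float]:
    """Single-variant view of :func:`segregation_test_all`."""
    chi2, df, p = segregation_test_all(genotypes, pedigree)
    i = variant_index
    return float(chi2[i]), int(df[i]), float(p[i])


def no_inconsistency_probability(allele_freq: float | np.ndarray,
                                 n_pairs: int | np.ndarray) -> float | np.ndarray:
    """Probability that ``n_pairs`` independent Hardy-Weinberg
    parent-offspring pairs show zero opposite homozygotes by chance,
    P = (1 - 2 (1-p)^2 p^2)^n_pairs.

    Small values mean absence of observed inconsistencies is informative;
    the filter keeps variants with P below a stringent threshold (1e-12).
    """
    p = np.asarray(allele_freq, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele_freq must be in [0, 1]")
    pr = (1.0 - 2.0 * (1 - p) ** 2 * p ** 2) ** np.asarray(n_pairs)
    return pr if pr.ndim else float(pr)


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds of the genetic-rule filters."""

    hwe_alpha: float = 0.05            # keep p > alpha
    segregation_alpha: float = 0.05    # keep p > alpha
    max_inconsistencies: int = 1
    chance_prob_max: float = 1e-12     # keep P < this
    min_maf: float = 0.01
    max_missing_rate: float = 0.05
    hwe_founders_only: bool = False
    min_expected_count: float = 5.0    # flag-only small-sample warning


@dataclass
class VariantQCReport:
    per_variant: pd.DataFrame
    attrition: dict[str, int]
    thresholds: QCThresholds
    chance_prob_formula: str = CHANCE_PROB_FORMULA
    notes: list[str] = field(default_factory=list)


_FILTERS = ["hwe", "segregation", "inconsistencies", "chance_prob",
            "maf", "missing", "monomorphic"]


def apply_variant_filters(genotypes: GenotypeMatrix, pedigree: Pedigree,
                          thresholds: QCThresholds = QCThresholds(),
                          ) -> tuple[GenotypeMatrix, VariantQCReport]:
    """Apply the genetic-rule filters and the final opposite-homozygote
    masking; returns the filtered matrix and a per-variant report."""
    t = thresholds
    calls = genotypes.calls
    n = (calls != MISSING).sum(axis=1)
    alt = np.where(calls == MISSING, 0, calls).sum(axis=1)
    freq = np.divide(alt, 2 * n, out=np.zeros(len(n)), where=n > 0)
    maf = np.minimum(freq, 1 - freq)
    missing_rate = (calls == MISSING).mean(axis=1)

    if t.hwe_founders_only:
        founder_cols = [j for j, s in enumerate(genotypes.sample_ids)
                        if pedigree.parents_of(s) == (None, None)]
        hwe_counts = _genotype_counts(calls[:, founder_cols])
    else:
        hwe_counts = _genotype_counts(calls)
    ok = hwe_counts.sum(axis=1) > 0
    hwe_chi2 = np.zeros(len(ok))
    hwe_p = np.ones(len(ok))
    if ok.any():
        hwe_chi2[ok], hwe_p[ok] = hwe_test_many(hwe_counts[ok])

    seg_chi2, seg_df, seg_p = segregation_test_all(genotypes, pedigree)
    incons = count_inconsistencies_per_variant(genotypes, pedigree)

    pairs = pedigree.parent_offspring_pairs(genotypes.sample_ids)
    col = {s: j for j, s in enumerate(genotypes.sample_ids)}
    n_pairs = np.zeros(genotypes.n_variants, dtype=np.int64)
    for parent, child in pairs:
        n_pairs += (calls[:, col[parent]] != MISSING) \
            & (calls[:, col[child]] != MISSING)
    chance_p = no_inconsistency_probability(freq, n_pairs)

    passes = {
        "hwe": hwe_p > t.hwe_alpha,
        "segregation": seg_p > t.segregation_alpha,
        "inconsistencies": incons <= t.max_inconsistencies,
        "chance_prob": chance_p < t.chance_prob_max,
        "maf": maf >= t.min_maf,
        "missing": missing_rate <= t.max_missing_rate,
        "monomorphic": (freq > 0) & (freq < 1),
    }
    keep = np.ones(genotypes.n_variants, dtype=bool)
    attrition: dict[str, int] = {"input": genotypes.n_variants}
    for name in _FILTERS:
        removed = keep & ~passes[name]
        attrition[f"removed_by_{name}"] = int(removed.sum())
        keep &= passes[name]
    attrition["after_filters"] = int(keep.sum())

    report = pd.DataFrame({
        "chrom": genotypes.chroms, "position": genotypes.positions,
        "allele_freq": freq, "maf": maf, "missing_rate": missing_rate,
        "hwe_chi2": hwe_chi2, "hwe_p": hwe_p,
        "segregation_chi2": seg_chi2, "segregation_df": seg_df,
        "segregation_p": seg_p, "inconsistency_count": incons,
        "n_pairs": n_pairs, "chance_prob": chance_p,
    })
    for name in _FILTERS:
        report[f"pass_{name}"] = passes[name]
    n_hwe = hwe_counts.sum(axis=1)
    exp_min = np.minimum(n_hwe * np.minimum(freq, 1 - freq) ** 2,
                         2 * n_hwe * freq * (1 - freq))
    report["small_sample_flag"] = exp_min < t.min_expected_count

    filtered = genotypes.subset_variants(keep)
    notes: list[str] = []
    if keep.sum() == 0:
        notes.append("warning: empty panel after filters")
        report["final_keep"] = keep
        return filtered, VariantQCReport(report, attrition, t, notes=notes)

    # final editions: mask remaining opposite homozygotes, then re-check
    # missingness and monomorphism on the masked panel
    records = find_mendelian_inconsistencies(filtered, pedigree)
    masked = mask_incompatible_genotypes(filtered, records)
    attrition["genotypes_masked"] = sum(1 + len(r.parents) for r in records)
    m_missing = (masked.calls == MISSING).mean(axis=1)
    m_n = (masked.calls != MISSING).sum(axis=1)
    m_alt = np.where(masked.calls == MISSING, 0, masked.calls).sum(axis=1)
    m_freq = np.divide(m_alt, 2 * m_n, out=np.zeros(len(m_n)), where=m_n > 0)
    keep2 = (m_missing <= t.max_missing_rate) & (m_freq > 0) & (m_freq < 1)
    attrition["removed_by_final_editions"] = int((~keep2).sum())
    final = masked.subset_variants(keep2)
    attrition["final"] = final.n_variants

    final_keep = keep.copy()
    final_keep[np.flatnonzero(keep)] = keep2
    report["final_keep"] = final_keep
    return final, VariantQCReport(report, attrition, t, notes=notes)
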