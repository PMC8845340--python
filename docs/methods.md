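# Methods

## Problem and approach

Population-based phasing programs reconstruct haplotypes statistically, and
their accuracy must be measured against a gold standard. In a sequenced
pedigree the gold standard comes for free: when at least one parent of an
individual is genotyped, Mendelian segregation rules resolve the parental
origin of many of its alleles exactly — exactly, that is, in the absence of
genotyping and marker-order errors, which is why the evaluation pipeline
couples the phasing metrics to a stringent pedigree-genetics QC of variants
and genomic regions, with crossover counts per meiosis as the headline
data-quality diagnostic.

The package implements the whole loop: a pedigree genotype simulator with
ground truth, site-wise trio phasing, variant and region QC, crossover
detection, and the metric suite (switch errors, quality-adjusted block
lengths, QAN50, pairwise accuracy). Because the motivating cattle data are
not public, every stage is exercised and validated on synthetic data whose
statistical structure mirrors that setting.

## Gold standard (trio phasing)

`phase_trio_site` resolves one site of one trio by enumeration: each parent
can transmit the alleles compatible with its genotype (both alleles when
heterozygous or missing), and the site is assigned iff exactly one
(paternal, maternal) combination is compatible with the child's genotype.
No compatible combination is a Mendelian inconsistency; sites with both
parents heterozygous (child heterozygous) stay unphased. Duos use the same
rule with the absent parent coded missing, which reduces to
"parent homozygous forces its side; the other side follows by genotype
subtraction". The site-wise rule is deliberate: no linkage or LD inference
enters the gold standard, so it is exact on error-free data — a guarantee
the test suite asserts against simulation truth. `hapA` is paternal by
convention.

All 64 genotype configurations are tabulated once and applied to whole
matrices by indexing, so pedigree-scale phasing is vectorised.

When masking inconsistencies, every member of the conflicting family (both
sides of an opposite-homozygote pair; all three of an impossible trio) is
set to missing at that site: the true error source is unknown.

## Variant QC

Filters, all computed on the same pre-masking snapshot of the genotype
matrix (so individual filters commute):

* **Hardy-Weinberg**: Pearson 1-df chi-square on genotype counts, keep
  p > 0.05. All genotyped individuals enter by default; pedigree
  non-independence turns out to inflate the test only marginally
  (measured ~4.8% rejection at the default 264-individual pedigree); a
  founders-only mode is available.
* **Offspring segregation**: trio offspring pooled by informative mating
  type — het x het expects 1:2:1 (2 df), het x hom expects 1:1 (1 df) —
  with component chi-squares and dfs summed; keep p > 0.05. Duos are not
  usable (the unobserved parent leaves the mating type undetermined).
  No continuity correction; cells with expected counts below 5 are flagged,
  not blocking. At ~98 trios the discrete chi-square is slightly
  *conservative* (3.5–4.5% rejection at nominal 5%); calibration converges
  to nominal by ~500 trios. It is never anticonservative, so the filter
  errs toward keeping true variants.
* **Mendelian inconsistencies**: keep iff the total count of
  opposite-homozygote pairs plus impossible trios over the entire pedigree
  is at most 1.
* **Chance probability**: keep iff the probability of observing zero
  opposite homozygotes by chance, were the variant an artifact with
  independent Hardy-Weinberg genotypes in each of the n parent-offspring
  pairs, is below 1e-12: P = (1 − 2(1−p)²p²)^n. This is a reconstruction —
  the threshold is standard, the formula is this package's reading — and it
  is logged in every report. It is stringent: with 279 pairs only variants
  with MAF above roughly 0.3 can pass (P first crosses 1e-12 at n = 207
  pairs for p = 0.5), so it dominates the attrition on synthetic panels
  with uniform frequencies.
* **MAF ≥ 0.01, missingness ≤ 5%, non-monomorphic.**

"Final editions" then mask remaining opposite homozygotes and re-check
missingness and monomorphism on the masked panel.

## Crossover detection and region QC

For each parent-offspring pair the transmitted allele from the focal parent
is deduced where the child is homozygous or the other parent homozygous;
where the parent is phased-heterozygous this pins the transmitted
haplotype (the origin). Crossovers are origin changes between runs of at
least `min_support = 3` informative sites; shorter runs are masked as
noise, since an isolated genotyping error otherwise fabricates a double
crossover. The default of 3 keeps double-crossover sensitivity at sequence
density while absorbing isolated errors (measured inflation < 5% at error
rate 1e-3). Localization intervals run from the last supporting site on
one side to the first on the other.

Interval recombination rates distribute each call uniformly (1/m) over the
m adjacent-marker intervals its localization spans — unbiased under uniform
localization uncertainty, at the cost of diluting sharp peaks when
informative sites are sparse.

Map-error candidates are marker runs bounded by two intervals with rate
above 0.05 and spanning at most 1 Mb. For each candidate the majority
origin inside the region is compared, across meioses, with the flanking
majority origin (50 informative sites each side), restricted to the
*non-recombinant majority* — meioses whose two flanks agree. This
conditioning is the package's design choice where the procedure was
genuinely open: it separates a genuine double-sided hotspot (region equals
flanks for every non-recombinant meiosis, r² ≈ 1) from a misplaced
assembly block (region segregates independently, r² ≈ 0). Candidates with
r² < 0.90 are masked, rates are recomputed from the surviving markers, and
the procedure iterates until silent. Chromosome extremities with inflated
terminal rates are flagged outright. High-coverage windows (> 6x the
individual's own mean, unioned across individuals) and 10-kb chromosome
ends complete the exclusion mask.

## Phasing metrics

All metrics are relative to *informative* sites: heterozygous and phased in
the truth, with concordant genotypes in the evaluated set. Genotype
discordance is reported separately — orientation is undefined there — a
case the package must decide because arbitrary VCFs are accepted.

Per individual and chromosome, each phased informative site has an
orientation (same/flipped vs truth); switch errors are orientation changes
between consecutive phased sites, with unphased sites skipped *without
breaking the chain* (two switch events inside one skipped gap cancel).
SER divides SEC by the count of informative markers (the literal
definition); the per-compared-pair variant is also reported. Blocks are
maximal constant-orientation runs; raw length is the first-to-last
compared-site distance (switch gaps belong to neither block); the QA
multiplier is block-local (phased fraction of the block's informative
sites), with the global-yield variant available — the two coincide at 100%
yield, where the adjustment is irrelevant anyway. QAN50 is the largest QA
length such that blocks at least that long hold half of all informative
SNPs. Pairwise accuracy (probability of equal orientation at a given
separation) is computed exhaustively with prefix sums — linear time per
chromosome — so the subsampling that a quadratic pairing would need never
engages. Genome fractions use the informative span (first-to-last
informative site per chromosome) as denominator, not assembly lengths.
Medians across individuals use the standard midpoint convention.

## Synthetic data: what it states and what it omits

Defaults state the motivating study's world: 29 autosomes, ~2.5 Gb,
24.5 Morgans sex-averaged with male/female multipliers 26/24.5 and
23/24.5; a pedigree of 264 individuals — 83 founders, 83 duo offspring
(one sampled parent), 98 trio offspring — giving 98 trios and 279
genotyped parent-offspring pairs. The duo layer matters: with trios alone
(196 pairs) the 1e-12 chance-probability filter is unsatisfiable for any
allele frequency. Founder haplotypes are site-wise Bernoulli draws from
uniform [0.05, 0.95] frequencies, optionally with a first-order
copy-your-neighbour dependence (`ld_copy_prob`) as a crude long-range-LD
stand-in — it is not calibrated to any real LD decay. Crossovers are a
pure Poisson process on the cM scale (no interference), positions mapped
to bp by linear interpolation; genotype errors replace the code by a
uniform draw among the other two codes; marker density and noise rates are
analysis dials, defaulting to modest density and zero noise.

The corruptor stands in for an imperfect population phaser: cumulative
label swaps at Poisson long-switch breakpoints, independent per-site point
switches, and random unphasing of heterozygous sites, all logged so every
downstream metric has an event-level oracle. Artifact variants (iid
Hardy-Weinberg, or all-carriers-heterozygous) and relocated marker blocks
(excise-and-reinsert assembly arithmetic keeping coordinates unique and
ordered) give the QC stages known targets.

A green test on this generator establishes correctness of the *methods*
under their stated assumptions. It does not establish robustness to real
sequence pathologies the generator omits: LD beyond first order, crossover
interference, allele-specific error modes, depth-correlated genotype
quality, segmental duplications, or reference-bias artifacts.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; VCF/map I/O converts.
Monomorphic variants get HWE p = 1 by convention; variants with no
informative matings get segregation p = 1 and df = 0. Chromosomes with
fewer than two compared sites yield SEC = 0 with a degenerate flag; empty
informative sets yield NaN metrics with a warning. Singleton blocks have
raw length 0. Empty pairwise bins are missing values, not zeros.
Majority-origin votes round half to even; r² over fewer than 20 complete
meioses is skipped with a warning; constant-vector correlations degenerate
to 1 when region equals flank and are otherwise indeterminate and skipped.
All randomness flows through explicit integer seeds; identical
configuration and seed reproduce results bit for bit.

## Known limitations

* The chance-probability formula is one defensible reconstruction of an
  under-specified rule; its report field says so.
* The marker-confidence-score machinery of pedigree linkage software is
  out of scope; the r²-based surrogate above takes its place and is
  recorded as such in reports.
* Depth is consumed as precomputed window summaries; no BAM processing.
* The segregation test's small-sample conservativeness (above) means
  nominal-α expectations are only met asymptotically in trio count.
* Scenario handling controls the evaluation cohort (trio offspring only,
  or trio plus duo offspring); it does not re-run external phasers, which
  users supply as phased VCFs.
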