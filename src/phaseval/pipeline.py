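"""End-to-end driver: simulate (optional) -> trio-phase -> variant QC ->
crossover QC -> region QC -> evaluate, with file artifacts per stage.

Two evaluation scenarios mirror the common benchmarking setups: the
``validation_only`` cohort contains only trio offspring (both parents
genotyped — the individuals whose gold standard is most complete) while
``full_cohort`` adds the duo offspring whose gold standard is partially
resolved. Founders have no parental information and are never evaluable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .crossover import analyze_meioses, co_summary
from .mendel import find_mendelian_inconsistencies, phase_pedigree
from .metrics import EvalReport, evaluate
from .model import GenotypeMatrix, HaplotypeSet, Pedigree
from .qc_regions import (build_exclusion_mask, flag_high_coverage_regions,
                         flag_map_error_regions)
from .qc_variants import QCThresholds, apply_variant_filters
from .sim import SimConfig, corrupt_haplotypes, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    scenario: str = "validation_only"      # or "full_cohort"
    # inputs: either simulate=True, or supply genotype_vcf + fam (+ map)
    simulate: bool = True
    sim: SimConfig | None = None
    genotype_vcf: str | None = None
    truth_vcf: str | None = None
    inferred_vcf: str | None = None
    fam: str | None = None
    depth_bed: str | None = None
    # stand-in phaser (used when no inferred_vcf is given): corruption rates
    long_switch_rate_per_Mb: float = 0.05
    point_switch_rate_per_site: float = 1e-4
    unphase_fraction: float = 0.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    min_support: int = 3
    end_trim_bp: int = 10_000
    coverage_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.scenario not in ("validation_only", "full_cohort"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "qc"},
                  qc=QCThresholds(**raw.get("qc", {})) if "qc" in raw
                  else QCThresholds())
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _check_inputs(config: PipelineConfig) -> None:
    if config.simulate:
        return
    for name in ("genotype_vcf", "fam"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name} missing: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of produced artifacts and the
    headline numbers. Fails fast with the stage name on any error."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(dataclasses.asdict(config)),
                      "stages": {}}

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = config.sim or SimConfig(
                n_chrom=3, n_variants_per_chrom=2000, seed=config.seed)
            if sim_cfg.seed != config.seed:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            sim = simulate_dataset(sim_cfg)
            genotypes, pedigree = sim.observed, sim.pedigree
            io.write_genotypes(genotypes, out / "observed.vcf")
            io.write_haplotypes(sim.truth_haps, out / "truth.vcf")
            io.write_pedigree(pedigree, out / "pedigree.fam")
            io.write_marker_map(sim.marker_map, out / "markers.map")
            manifest["stages"][stage] = {
                "observed": "observed.vcf", "truth": "truth.vcf",
                "fam": "pedigree.fam", "map": "markers.map"}
        else:
            sim = None
            genotypes = io.read_genotypes(config.genotype_vcf)
            pedigree = io.read_pedigree(config.fam)
            manifest["stages"][stage] = {"observed": config.genotype_vcf}

        stage = "trio_phase"
        gold = phase_pedigree(genotypes, pedigree)
        records = find_mendelian_inconsistencies(genotypes, pedigree)
        io.write_haplotypes(gold, out / "gold.vcf")
        pd.DataFrame([{"variant_index": r.variant_index,
                       "offspring": r.offspring,
                       "parents": ",".join(r.parents), "kind": r.kind}
                      for r in records]).to_csv(
            out / "inconsistencies.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "gold": "gold.vcf", "inconsistencies": "inconsistencies.tsv",
            "n_inconsistencies": len(records)}

        stage = "qc_variants"
        filtered, qc_report = apply_variant_filters(genotypes, pedigree,
                                                    config.qc)
        io.write_genotypes(filtered, out / "filtered.vcf")
        qc_report.per_variant.to_csv(out / "variant_qc.tsv", sep="\t",
                                     index=False)
        (out / "attrition.json").write_text(json.dumps(qc_report.attrition,
                                                       indent=2))
        manifest["stages"][stage] = dict(qc_report.attrition)

        stage = "count_co"
        parent_haps = sim.truth_haps if sim is not None else gold
        calls, origins = analyze_meioses(parent_haps, genotypes, pedigree,
                                         config.min_support)
        meioses = sorted({(ov.parent, ov.child) for ov in origins})
        morgans = (sim.config.n_chrom * sim.config.chrom_cM_length / 100
                   if sim is not None else None)
        co_df, co_sum = co_summary(calls, pedigree, expectation=morgans,
                                   meioses=meioses)
        pd.DataFrame([{"chrom": c.chrom, "start": c.start, "end": c.end,
                       "parent": c.parent, "child": c.child}
                      for c in calls]).to_csv(out / "crossovers.tsv",
                                              sep="\t", index=False)
        co_df.to_csv(out / "co_per_meiosis.tsv", sep="\t", index=False)
        manifest["stages"][stage] = co_sum

        stage = "qc_regions"
        map_mask, flag_report = flag_map_error_regions(
            origins, min_support=config.min_support)
        masks = [map_mask]
        if config.depth_bed:
            depth = io.read_depth_track(config.depth_bed)
            masks.append(flag_high_coverage_regions(depth,
                                                    config.coverage_factor))
        chrom_lengths = {c: int(genotypes.positions[sl].max()) + 1
                         for c, sl in genotypes.iter_chromosomes()}
        if sim is not None:
            chrom_lengths = {c: sim.config.chrom_bp_length
                             for c in chrom_lengths}
        exclusion = build_exclusion_mask(chrom_lengths, *masks,
                                         end_trim_bp=config.end_trim_bp)
        io.write_region_mask(exclusion, out / "exclusion.bed")
        flag_report.to_csv(out / "map_error_candidates.tsv", sep="\t",
                           index=False)
        manifest["stages"][stage] = {
            "exclusion": "exclusion.bed", "n_intervals": len(exclusion),
            "masked_bp": exclusion.total_bp()}

        stage = "evaluate"
        if config.inferred_vcf:
            inferred = io.read_haplotypes(config.inferred_vcf)
        elif sim is not None:
            inferred, corr_log = corrupt_haplotypes(
                sim.truth_haps, config.long_switch_rate_per_Mb,
                config.point_switch_rate_per_site, config.unphase_fraction,
                seed=config.seed + 1)
            corr_log.to_csv(out / "corruptions.tsv", sep="\t", index=False)
        else:
            raise FileNotFoundError("no inferred haplotypes to evaluate")
        cohort = _evaluation_cohort(config.scenario, pedigree,
                                    genotypes.sample_ids)
        report = evaluate(gold, inferred, individuals=cohort)
        write_report(report, out)
        manifest["stages"][stage] = report.summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _evaluation_cohort(scenario: str, pedigree: Pedigree,
                       sample_ids: list[str]) -> list[str]:
    trios = {c for c, _, _ in pedigree.find_trios(sample_ids)}
    if scenario == "validation_only":
        return [s for s in sample_ids if s in trios]
    duos = {c for c, _ in pedigree.find_duos(sample_ids)}
    return [s for s in sample_ids if s in trios or s in duos]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: EvalReport, out_dir: str | Path) -> None:
    """Serialize an evaluation report: per-individual TSV, QAN curve,
    genome-fraction and pairwise TSVs, plus a JSON twin of the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_individual.to_csv(out / "per_individual.tsv", sep="\t",
                                 index=False)
    report.qan.to_csv(out / "qan_curve.tsv", sep="\t", index=False)
    report.genome_fraction.to_csv(out / "genome_fraction.tsv", sep="\t",
                                  index=False)
    report.pairwise.to_csv(out / "pairwise_accuracy.tsv", sep="\t",
                           index=False)
    (out / "summary.json").write_text(json.dumps(_jsonable(report.summary),
                                                 indent=2))


def make_report(out_dir: str | Path) -> dict:
    """Re-assemble the consolidated summary from stage outputs on disk; the
    JSON twin must round-trip the TSV content."""
    out = Path(out_dir)
    summary = json.loads((out / "summary.json").read_text())
    per_ind = pd.read_csv(out / "per_individual.tsv", sep="\t")
    for metric in ("sec", "ser", "yield", "qan50"):
        s = per_ind[metric].dropna()
        if len(s):
            recomputed = {"min": float(s.min()), "mean": float(s.mean()),
                          "median": float(s.median()), "max": float(s.max())}
            if not all(np.isclose(recomputed[k], summary[metric][k])
                       for k in recomputed):
                raise ValueError(f"summary/{metric} does not round-trip")
    return summary
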