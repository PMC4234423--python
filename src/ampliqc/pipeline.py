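"""Pipeline orchestration: one config drives simulate -> coverage-qc ->
reproducibility -> validate -> concordance, writing a machine-readable
report bundle (JSON index plus per-stage TSVs).

Logs go to stderr; results only to files. Exit semantics used by the
CLI: missing input -> 2, invariant violation in a stage -> 3.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    AmpliQCError,
    read_amplicon_bed,
    read_bed,
    read_depth_table,
    read_mutation_table,
    read_qpcr_table,
    read_variant_calls,
    write_amplicon_bed,
    write_bed,
    write_depth_table,
    write_matrix_tsv,
    write_qpcr_table,
    write_sample_metrics,
    write_variant_calls,
    mutation_table_records,
)
from . import coverage_qc, replicate_concordance, reproducibility
from .synthetic_data import SimulationParams, simulate_all
from .variant_validation import validate_mutations, validation_rate

log = logging.getLogger("ampliqc")

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "min_cov": 20.0,
    "min_sample_frac": 0.8,
    "cq_threshold": 29.0,
    "cq_max": 35.0,
    "fluor_min": 100.0,
    "cov_max": 2.0,
    "min_callable_depth": 20,
    "homopolymer_min": 5,
    "dinuc_min_units": 4,
    "uniformity_bands": [[0.2, 5.0], [0.5, 2.0]],
}


@dataclass
class RunConfig:
    """Inputs (paths or simulation parameters), thresholds and output dir.

    Absent thresholds take the module defaults; the config round-trips
    through YAML/JSON serialization.
    """

    out_dir: str = "ampliqc_out"
    seed: int = 0
    simulate: dict | None = None  # SimulationParams fields
    depth: str | None = None
    amplicons: str | None = None
    exons: str | None = None
    qpcr: str | None = None
    calls: str | None = None
    mutations: str | None = None
    thresholds: dict = field(default_factory=dict)

    def threshold(self, name: str):
        return self.thresholds.get(name, DEFAULT_THRESHOLDS[name])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str | None, what: str) -> str:
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(f"missing input for {what}: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config enables, in dependency order.

    Returns the report index (also written to ``<out>/report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: config.threshold(k) for k in DEFAULT_THRESHOLDS},
        "inputs": {},
        "stages": {},
    }

    if config.simulate is not None:
        log.info("simulating input data")
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        params = SimulationParams.from_dict(sim)
        bundle = simulate_all(params)
        sim_dir = out / "simulated"
        sim_dir.mkdir(exist_ok=True)
        write_amplicon_bed(bundle.panel, sim_dir / "amplicons.bed")
        write_bed(bundle.exons, sim_dir / "exons.bed")
        write_depth_table(bundle.tracks, sim_dir / "depth.tsv")
        write_qpcr_table(bundle.wells, sim_dir / "qpcr.csv")
        write_variant_calls(bundle.calls, sim_dir / "calls.vcf",
                            samples=bundle.samples)
        write_sample_metrics(bundle.metrics, sim_dir / "sample_metrics.tsv")
        with open(sim_dir / "truth.json", "w") as fh:
            json.dump({
                "variants": [list(v) for v in bundle.truth.variants],
                "deletions": [list(d) for d in bundle.truth.deletions],
                "amplicon_efficiency": bundle.truth.amplicon_efficiency,
                "sample_scale": bundle.truth.sample_scale,
            }, fh, indent=1, sort_keys=True)
        config.depth = str(sim_dir / "depth.tsv")
        config.amplicons = str(sim_dir / "amplicons.bed")
        config.exons = str(sim_dir / "exons.bed")
        config.qpcr = str(sim_dir / "qpcr.csv")
        config.calls = str(sim_dir / "calls.vcf")
        report["stages"]["simulate"] = {"params": params.to_dict(),
                                        "dir": str(sim_dir)}

    panel = exons = tracks = wells = calls = None
    if config.amplicons:
        panel = read_amplicon_bed(_require(config.amplicons, "amplicons"))
    if config.exons:
        exons = read_bed(_require(config.exons, "exons"))
    if config.depth:
        tracks = read_depth_table(_require(config.depth, "depth"))
    if config.qpcr:
        wells = read_qpcr_table(_require(config.qpcr, "qpcr"))
    if config.calls:
        calls = read_variant_calls(_require(config.calls, "calls"))
    for key in ("depth", "amplicons", "exons", "qpcr", "calls", "mutations"):
        p = getattr(config, key)
        if p and os.path.exists(p):
            report["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    if tracks and panel:
        log.info("coverage QC over %d samples x %d assays",
                 len(tracks), len(panel))
        targets = {"amplicon": [a.region for a in panel]}
        if exons:
            targets["exon"] = exons
        summaries = []
        bands_rows = []
        for t in tracks:
            for tset, regs in targets.items():
                s = coverage_qc.per_sample_stats(t, regs, tset)
                summaries.append(vars(s))
                norm = coverage_qc.normalize_track(t, regs)
                for lo, hi in config.threshold("uniformity_bands"):
                    u = coverage_qc.uniformity_fraction(norm, lo, hi, regs, tset)
                    bands_rows.append({"sample": t.sample, **vars(u)})
        pd.DataFrame(summaries).to_csv(out / "coverage_summary.tsv",
                                       sep="\t", index=False)
        pd.DataFrame(bands_rows).to_csv(out / "uniformity.tsv",
                                        sep="\t", index=False)
        succ, any_frac, flags = coverage_qc.assay_success_rates(
            tracks, panel, config.threshold("min_cov"),
            config.threshold("min_sample_frac"))
        pd.DataFrame({"assay_id": list(flags), "success": list(flags.values())}
                     ).to_csv(out / "assay_success.tsv", sep="\t", index=False)
        for tset, regs in targets.items():
            for mode in ("per_base_mean", "pooled"):
                x, fr = coverage_qc.cumulative_distribution(tracks, regs, mode)
                step = max(1, len(x) // 500)
                pd.DataFrame({"normalized_coverage": x[::step],
                              "fraction_of_bases": fr[::step]}).to_csv(
                    out / f"coverage_cdf_{tset}_{mode}.tsv", sep="\t",
                    index=False)
        report["stages"]["coverage_qc"] = {
            "success_fraction": succ, "any_sample_fraction": any_frac}

    if tracks and panel and len(tracks) >= 2:
        log.info("reproducibility analysis")
        amp_regions = [a.region for a in panel]
        matrix = reproducibility.correlation_matrix(tracks, amp_regions)
        write_matrix_tsv(matrix.samples, matrix.values,
                         out / "coverage_correlation.tsv")
        summ = reproducibility.summarize_matrix(matrix)
        stage: dict[str, Any] = {"spearman_mean": summ.mean,
                                 "spearman_sd": summ.sd,
                                 "n_pairs": summ.n_pairs,
                                 "n_missing": summ.n_missing}
        if wells:
            stage["dropout_rate"] = reproducibility.dropout_rate(
                wells, config.threshold("cq_threshold"))
            cov_map = reproducibility.assay_mean_coverage(tracks, panel)
            try:
                stage["cq_coverage_r2"] = reproducibility.cq_coverage_association(
                    wells, panel, cov_map,
                    cq_dropout_threshold=config.threshold("cq_threshold"))
            except AmpliQCError as exc:
                stage["cq_coverage_r2"] = None
                log.warning("cq-coverage association skipped: %s", exc)
        report["stages"]["reproducibility"] = stage

    if config.mutations:
        log.info("mutation rediscovery validation")
        df = read_mutation_table(_require(config.mutations, "mutations"))
        mutations = mutation_table_records(df)
        results = validate_mutations(
            mutations, calls or [], tracks or [], wells or [], panel or [],
            min_callable_depth=config.threshold("min_callable_depth"),
            cq_max=config.threshold("cq_max"),
            fluor_min=config.threshold("fluor_min"),
            cov_max=config.threshold("cov_max"))
        pd.DataFrame([{
            "gene": r.mutation.gene, "sample": r.mutation.sample,
            "chrom": r.mutation.chrom, "pos": r.mutation.pos,
            "cdna": r.mutation.cdna, "status": r.status,
            "qpcr_call": r.qpcr_call, "ref_depth": r.ref_depth,
            "alt_depth": r.alt_depth} for r in results]).to_csv(
            out / "mutation_validation.tsv", sep="\t", index=False)
        v, n, frac = validation_rate(results)
        report["stages"]["validate"] = {"validated": v, "total": n,
                                        "fraction": frac}

    if calls and tracks and len(tracks) >= 2:
        log.info("replicate concordance (all samples as one replicate set)")
        by_sample: dict[str, list] = {}
        for c in calls:
            by_sample.setdefault(c.sample, []).append(c)
        track_ix = {t.sample: t for t in tracks}
        reps = [replicate_concordance.Replicate(s, cs, track_ix.get(s))
                for s, cs in sorted(by_sample.items())]
        if len(reps) >= 2:
            group = replicate_concordance.build_group(
                "all", reps, config.threshold("min_callable_depth"))
            report["stages"]["concordance"] = {
                "union": group.union_count,
                "intersect": group.intersect_count,
                "concordant": group.concordant,
                "discordant": group.discordant,
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def main_run(config: RunConfig) -> int:
    """Run with CLI exit semantics (0 ok, 2 missing input, 3 bad data)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    try:
        run_pipeline(config)
    except FileNotFoundError as exc:
        log.error("%s", exc)
        return 2
    except AmpliQCError as exc:
        log.error("invariant violation: %s", exc)
        return 3
    return 0
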