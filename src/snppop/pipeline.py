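"""Pipeline orchestration: simulate/load -> QC -> analyses -> report.

Stages run in dependency order; each writes its TSV/JSON artifacts and a
manifest entry (file, sha256, rows).  A failing stage halts its dependents
but independent stages continue.  All stage randomness is derived from one
root seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import (
    FilterConfig,
    GenotypePanel,
    OutlierModelConfig,
    RohConfig,
    SimulationConfig,
    diversity_table,
    detect_roh_all,
    distance_matrix,
    filter_snps,
    fst_components_table,
    group_mean_fst,
    ld_prune,
    nj_newick,
    pairwise_population_fst,
    pca,
    population_ld_fit,
    read_plink_text,
    roh_summary,
    scan_panel,
    simulate_genotypes,
)
from .panel import PanelError

log = logging.getLogger("snppop.pipeline")

ALL_STAGES = (
    "filter", "diversity", "distance", "pca", "fst", "ld", "roh", "selection",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (root_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results/pipeline"
    seed: int = 0
    simulation: SimulationConfig | None = None
    panel_prefix: str | None = None  # read .ped/.map/.pop instead of simulating
    stages: tuple[str, ...] = ALL_STAGES
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    prune_r2: float = 0.2
    pca_k: int = 4
    fst_grouping: dict[str, str] | None = None
    ld_population: str | None = None  # default: first population
    roh_config: RohConfig = field(default_factory=RohConfig)
    selection_contrast: dict[str, str] | None = None
    selection_config: OutlierModelConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PanelError(f"unknown stages {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    failed: set[str] = set()

    def record(stage: str, name: str, path: Path, rows: int | None) -> None:
        manifest["files"][name] = {
            "path": str(path), "sha256": _sha256(path), "rows": rows,
        }
        manifest["stages"].setdefault(stage, []).append(name)

    def run_stage(stage: str, fn) -> None:
        if stage not in config.stages:
            return
        t0 = time.time()
        try:
            fn()
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
        except Exception:
            failed.add(stage)
            log.exception("stage %s failed", stage)

    # -- input panel ------------------------------------------------------
    if config.panel_prefix is not None:
        prefix = config.panel_prefix
        panel = read_plink_text(f"{prefix}.ped", f"{prefix}.map", f"{prefix}.pop")
    elif config.simulation is not None:
        sim = config.simulation
        panel = simulate_genotypes(sim)
        (out / "simulation.config.json").write_text(sim.to_json())
        record("simulate", "simulation_config", out / "simulation.config.json", None)
    else:
        raise PanelError("config needs either a simulation or a panel prefix")

    state: dict[str, Any] = {"panel": panel}

    def do_filter() -> None:
        filtered, report = filter_snps(state["panel"], config.filter_config)
        state["panel"] = filtered
        _write_tsv(report, out / "filter_report.tsv")
        record("filter", "filter_report", out / "filter_report.tsv", len(report))

    def do_diversity() -> None:
        table = diversity_table(state["panel"])
        _write_tsv(table, out / "diversity.tsv")
        record("diversity", "diversity", out / "diversity.tsv", len(table))
        state["diversity"] = table

    def do_distance() -> None:
        dmat = distance_matrix(state["panel"])
        _write_tsv(dmat, out / "distance_matrix.tsv", index=True)
        record("distance", "distance_matrix", out / "distance_matrix.tsv", len(dmat))
        newick = nj_newick(dmat)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        record("distance", "nj_tree", out / "nj_tree.nwk", None)

    def do_pca() -> None:
        pruned, kept = ld_prune(state["panel"], r2_threshold=config.prune_r2)
        res = pca(pruned, k=min(config.pca_k, pruned.n_samples - 1))
        scores = pd.DataFrame(
            res.scores,
            index=res.samples,
            columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])],
        )
        scores.insert(0, "population", state["panel"].population_labels)
        _write_tsv(scores, out / "pca_scores.tsv", index=True)
        record("pca", "pca_scores", out / "pca_scores.tsv", len(scores))
        (out / "pca_eigen.json").write_text(
            json.dumps(
                {
                    "eigenvalues": res.eigenvalues.tolist(),
                    "explained": res.explained.tolist(),
                    "n_snps_used": res.n_snps_used,
                    "n_snps_pruned_panel": int(pruned.n_snps),
                },
                indent=2,
            )
        )
        record("pca", "pca_eigen", out / "pca_eigen.json", None)

    def do_fst() -> None:
        mean, sd, table = group_mean_fst(state["panel"], config.fst_grouping)
        _write_tsv(table, out / "fst_per_snp.tsv")
        record("fst", "fst_per_snp", out / "fst_per_snp.tsv", len(table))
        pair = pairwise_population_fst(state["panel"])
        _write_tsv(pair, out / "fst_pairwise.tsv", index=True)
        record("fst", "fst_pairwise", out / "fst_pairwise.tsv", len(pair))
        (out / "fst_summary.json").write_text(
            json.dumps({"mean": mean, "sd": sd}, indent=2)
        )
        record("fst", "fst_summary", out / "fst_summary.json", None)
        state["fst"] = (mean, sd)

    def do_ld() -> None:
        panel_ = state["panel"]
        pops = (
            [config.ld_population]
            if config.ld_population
            else panel_.population_names()
        )
        fits = {}
        for pop_name in pops:
            records, binned, fit = population_ld_fit(panel_, pop_name)
            _write_tsv(binned, out / f"ld_binned_{pop_name}.tsv")
            record("ld", f"ld_binned_{pop_name}", out / f"ld_binned_{pop_name}.tsv", len(binned))
            fits[pop_name] = {
                "beta_per_kb": fit.beta_per_kb,
                "extent_kb_r2_0.3": fit.extent_kb,
                "n_pairs": fit.n_pairs,
            }
        (out / "ld_fits.json").write_text(json.dumps(fits, indent=2))
        record("ld", "ld_fits", out / "ld_fits.json", None)
        state["ld"] = fits

    def do_roh() -> None:
        segments = detect_roh_all(state["panel"], config.roh_config)
        _write_tsv(segments, out / "roh_segments.tsv")
        record("roh", "roh_segments", out / "roh_segments.tsv", len(segments))
        sample_table, hist = roh_summary(segments, state["panel"])
        _write_tsv(sample_table, out / "roh_summary.tsv")
        record("roh", "roh_summary", out / "roh_summary.tsv", len(sample_table))
        _write_tsv(hist, out / "roh_histogram.tsv")
        record("roh", "roh_histogram", out / "roh_histogram.tsv", len(hist))

    def do_selection() -> None:
        contrast = config.selection_contrast
        if contrast is None:
            pops = state["panel"].population_names()
            contrast = {p: ("focal" if i == 0 else "rest") for i, p in enumerate(pops)}
        scan_cfg = config.selection_config or OutlierModelConfig.fast(
            seed=stage_seed(config.seed, "selection")
        )
        table = scan_panel(state["panel"], contrast, scan_cfg)
        _write_tsv(table, out / "selection_scan.tsv")
        record("selection", "selection_scan", out / "selection_scan.tsv", len(table))
        state["selection"] = table

    run_stage("filter", do_filter)
    run_stage("diversity", do_diversity)
    run_stage("distance", do_distance)
    run_stage("pca", do_pca)
    run_stage("fst", do_fst)
    run_stage("ld", do_ld)
    run_stage("roh", do_roh)
    run_stage("selection", do_selection)

    # summary report: per-population N_SNP / P_N / A_R / H_E / LD extent
    if "diversity" in state:
        report = state["diversity"].copy()
        if "ld" in state:
            report["r2_extent_0.3_kb"] = [
                state["ld"].get(p, {}).get("extent_kb_r2_0.3", np.nan)
                for p in report["population"]
            ]
        _write_tsv(report, out / "summary_report.tsv")
        record("report", "summary_report", out / "summary_report.tsv", len(report))

    manifest["failed_stages"] = sorted(failed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
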