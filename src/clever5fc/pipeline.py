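"""End-to-end orchestration: simulate -> QC -> pools -> per-cell calls ->
stage merge -> landscape metrics, with every result table written as TSV.

The pipeline is deterministic given the config (all randomness flows from
``config.seed``); re-running with the same config yields byte-identical
tables.  All results are computed in memory first and written in one pass at
the end, so a failing stage leaves no partial output behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import calling, io, metrics, simulate
from .config import RunConfig
from .errors import ConfigurationError, UndefinedRateError
from .genome import AnnotationSet, GenomeMap, Site, WindowGrid


@dataclass
class PipelineResult:
    genome: GenomeMap
    annotation: AnnotationSet
    truth: simulate.SyntheticTruth
    cells: list[simulate.SimulatedCell] = field(repr=False)
    qc: dict[str, calling.CellQC] = field(repr=False)
    candidate_pool: calling.SitePool = field(repr=False)
    noise_pool: calling.SitePool = field(repr=False)
    calls: dict[str, calling.FcCallSet] = field(repr=False)
    stages: dict[str, metrics.StageCallSet] = field(repr=False)
    marked: dict[str, "ann.MarkedWindows"] = field(repr=False)
    fpdr: float | None
    tables: dict[str, pd.DataFrame] = field(repr=False)
    log_lines: list[str] = field(repr=False)


def _pooled_background(cells: list[simulate.SimulatedCell],
                       cfg) -> float | None:
    """Across-cell lambda rate, the fallback when one cell lacks qualifying
    lambda sites."""
    nt = total = 0
    for cell in cells:
        df = cell.lambda_counts.data
        ok = (df["n_t"] + df["n_c"]) >= cfg.min_depth_lambda
        nt += int(df.loc[ok, "n_t"].sum())
        total += int(df.loc[ok, "n_t"].sum() + df.loc[ok, "n_c"].sum())
    return nt / total if total else None


def run_pipeline(config: RunConfig) -> PipelineResult:
    if len(config.treated) < 2:
        raise ConfigurationError("pipeline requires >= 2 treated cells")
    log: list[str] = []
    cfg = config.calling

    # --- synthetic inputs -------------------------------------------------
    genome, annotation = simulate.make_genome(
        config.n_chrom, config.chrom_len, config.cpg_density,
        annotation_spec=config.annotation_spec, seed=config.seed,
    )
    truth = simulate.make_truth(
        genome, annotation,
        class_rates=config.class_rates, seed=config.seed,
        base_rate=config.base_rate, conversion_eff=config.conversion_eff,
        background_rate=config.background_rate,
        coverage_mean=config.coverage_mean,
    )
    manifest = config.manifest
    cells = simulate.simulate_cells(
        truth,
        n_treated=len(config.treated),
        n_untreated=len(config.untreated),
        seed=config.seed,
        cell_ids=[c.cell_id for c in config.treated]
        + [c.cell_id for c in config.untreated],
        treatments=["treated"] * len(config.treated)
        + ["untreated"] * len(config.untreated),
    )
    by_id = {c.cell_id: c for c in cells}
    log.append(f"simulated {genome.n_sites} CpG sites, "
               f"{int(truth.formylated_mask.sum())} truly formylated, "
               f"{len(cells)} cells")

    snp_mask: frozenset[Site] = frozenset()
    if config.snp_mask_path:
        snp_mask = io.read_snp_mask(config.snp_mask_path)
        log.append(f"SNP mask: {len(snp_mask)} positions")

    # --- per-cell QC rates ------------------------------------------------
    pooled_bg = _pooled_background(cells, cfg)
    qc: dict[str, calling.CellQC] = {}
    for cell in cells:
        conv = calling.estimate_conversion_rate(cell.spikein)
        try:
            bg = calling.estimate_background_rate(cell.lambda_counts, cfg)
        except UndefinedRateError:
            if pooled_bg is None:
                raise
            bg = pooled_bg
            log.append(f"{cell.cell_id}: no qualifying lambda sites, "
                       "using pooled background rate")
        qc[cell.cell_id] = calling.CellQC(
            cell.cell_id, cell.treatment, conv, bg
        )

    # --- pools ------------------------------------------------------------
    treated_counts = [by_id[c.cell_id].counts for c in config.treated]
    untreated_counts = [by_id[c.cell_id].counts for c in config.untreated]
    candidate = calling.build_pool(treated_counts, "candidate", cfg)
    if untreated_counts:
        noise = calling.build_pool(untreated_counts, "noise", cfg)
    else:
        noise = calling.SitePool("noise", frozenset())
    log.append(f"candidate pool: {len(candidate)} sites; "
               f"noise pool: {len(noise)} sites")

    # --- per-cell calling (untreated too, for false-positive modeling) ----
    calls: dict[str, calling.FcCallSet] = {}
    for cell in cells:
        calls[cell.cell_id] = calling.call_cell(
            cell.counts, candidate, noise, snp_mask, qc[cell.cell_id], cfg
        )

    treated_calls = [calls[c.cell_id] for c in config.treated]
    untreated_calls = [calls[c.cell_id] for c in config.untreated]
    fpdr: float | None = None
    if untreated_calls:
        try:
            fpdr = calling.false_positive_detection_rate(
                treated_calls, untreated_calls
            )
            log.append(f"false-positive detection rate: {fpdr:.6g}")
        except UndefinedRateError:
            log.append("false-positive detection rate: undefined "
                       "(zero treated abundance)")
    else:
        log.append("false-positive detection rate: unavailable "
                   "(no untreated cells)")

    # --- stage merging and transitions ------------------------------------
    stage_order: list[str] = []
    for spec in config.treated:
        if spec.stage and spec.stage not in stage_order:
            stage_order.append(spec.stage)
    stages = {
        s: metrics.merge_stage(
            s, [calls[c.cell_id] for c in config.treated if c.stage == s]
        )
        for s in stage_order
    }
    transition_rows = []
    for a, b in zip(stage_order, stage_order[1:]):
        counts = metrics.stage_transition(stages[a], stages[b])
        transition_rows.append({"from": a, "to": b, **counts})

    # --- landscape metrics ------------------------------------------------
    grid = WindowGrid(config.window_size, genome.chromosomes)
    profiles = [
        metrics.window_profile(
            calls[c.cell_id].fc_sites, calls[c.cell_id].unmod_sites, grid,
            owner=c.cell_id,
        )
        for c in config.treated
    ]
    class_map = ann.window_class_map(grid, annotation)
    var_table, var_medians = metrics.window_stats(profiles, class_map)
    corr = metrics.correlation_cluster(profiles)

    background = frozenset().union(*(c.covered3 for c in treated_calls))
    merged_fc = frozenset().union(*(c.fc_sites for c in treated_calls))
    if merged_fc:
        enrichment = metrics.relative_enrichment(
            merged_fc, background, annotation
        ).reset_index()
    else:
        enrichment = pd.DataFrame(
            columns=["class", "n_fc_in", "n_fc_total", "n_bg_in",
                     "n_bg_total", "log2_enrichment"]
        )
        log.append("no 5fC sites called in treated cells; "
                   "enrichment table empty")

    marked = {
        s: ann.mark_windows(stages[s].merged_fc, grid) for s in stage_order
    }
    overlap_rows = []
    for a, b in zip(stage_order, stage_order[1:]):
        parts = metrics.shared_regions(marked[a], marked[b])
        overlap_rows.append(
            {"a": a, "b": b, "n_a_specific": parts["n_a_specific"],
             "n_shared": parts["n_shared"],
             "n_b_specific": parts["n_b_specific"]}
        )

    pair_rows = []
    pairs: dict[str, list] = {}
    for spec in config.manifest:
        if spec.pair_id:
            pairs.setdefault(spec.pair_id, []).append(spec)
    for pair_id, members in sorted(pairs.items()):
        if len(members) != 2:
            log.append(f"pair {pair_id}: expected 2 members, "
                       f"got {len(members)}; skipped")
            continue
        a, b = members
        diff = metrics.paired_difference(
            calls[a.cell_id], calls[b.cell_id], pair_id=pair_id
        )
        pair_rows.append(
            {"pair_id": pair_id, "member_a": a.cell_id, "member_b": b.cell_id,
             "diff_whole_genome": diff.diffs["whole_genome"]}
        )

    # --- result tables ----------------------------------------------------
    qc_rows = []
    for cell in cells:
        c = calls[cell.cell_id]
        q = qc[cell.cell_id]
        depth = cell.counts.depth
        qc_rows.append(
            {
                "cell_id": cell.cell_id,
                "treatment": cell.treatment,
                "conversion_rate": q.conversion_rate,
                "background_rate": q.background_rate,
                "cpg_ge1x": int((depth >= 1).sum()),
                "cpg_ge3x": int((depth >= 3).sum()),
                "cpg_ge5x": int((depth >= 5).sum()),
                "n_fc": len(c.fc),
                "n_unmod": len(c.unmod_sites),
                "abundance": c.abundance,
            }
        )
    stage_rows = [
        {
            "stage": s,
            "n_cells": len(stages[s].cells),
            "merged_fc": len(stages[s].merged_fc),
            "common_covered": len(stages[s].common_covered),
            "stage_fc_fraction": stages[s].stage_fc_fraction,
        }
        for s in stage_order
    ]
    attrition_rows = []
    for cell in cells:
        attrition_rows.append(
            {"cell_id": cell.cell_id, **calls[cell.cell_id].attrition}
        )

    cell_level_rows = [
        {"cell_id": c.cell_id, "stage": c.stage or "",
         "level": metrics.fc_level(calls[c.cell_id])}
        for c in config.treated
    ]

    tables = {
        "qc_summary": pd.DataFrame(qc_rows),
        "cell_levels": pd.DataFrame(cell_level_rows),
        "window_overlap": pd.DataFrame(
            overlap_rows,
            columns=["a", "b", "n_a_specific", "n_shared", "n_b_specific"],
        ),
        "stage_levels": pd.DataFrame(stage_rows),
        "transitions": pd.DataFrame(
            transition_rows,
            columns=["from", "to", "inherited", "newly_generated",
                     "undetermined"],
        ),
        "enrichment": enrichment,
        "window_variance": var_table,
        "variance_medians": (
            var_medians.reset_index()
            if var_medians is not None
            else pd.DataFrame(columns=["cls", "median_variance"])
        ),
        "correlation": corr.rho.reset_index(names="cell_id"),
        "paired_diff": pd.DataFrame(
            pair_rows,
            columns=["pair_id", "member_a", "member_b", "diff_whole_genome"],
        ),
        "attrition": pd.DataFrame(attrition_rows),
    }
    return PipelineResult(
        genome=genome, annotation=annotation, truth=truth, cells=cells,
        qc=qc, candidate_pool=candidate, noise_pool=noise, calls=calls,
        stages=stages, marked=marked, fpdr=fpdr, tables=tables,
        log_lines=log,
    )


def write_results(result: PipelineResult, outdir: str | Path,
                  write_counts: bool = False) -> Path:
    """Write every result table plus per-cell call files and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        io.write_table(table, outdir / f"{name}.tsv")
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for cell_id, callset in result.calls.items():
        io.write_calls(callset, calls_dir / f"{cell_id}.calls.tsv")
    if write_counts:
        counts_dir = outdir / "counts"
        counts_dir.mkdir(exist_ok=True)
        for cell in result.cells:
            io.write_counts_table(cell.counts,
                                  counts_dir / f"{cell.cell_id}.counts.tsv")
            io.write_control_table(
                cell.spikein, counts_dir / f"{cell.cell_id}.spikein.tsv")
            io.write_control_table(
                cell.lambda_counts, counts_dir / f"{cell.cell_id}.lambda.tsv")
    io.write_table(result.truth.to_frame(), outdir / "truth.tsv")
    for stage, mw in result.marked.items():
        with open(outdir / f"marked_windows_{stage}.bed", "w") as fh:
            size = mw.window_size
            for chrom, start in sorted(mw.windows):
                end = min(start + size, result.genome.chromosomes[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\n")
    lines = list(result.log_lines)
    if result.fpdr is not None:
        lines.append(f"FPDR\t{result.fpdr:.10g}")
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
    return outdir
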