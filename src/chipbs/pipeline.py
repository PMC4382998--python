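"""End-to-end pipeline: simulation/inputs -> calls -> peaks -> tests -> profiles.

``run_pipeline`` chains every stage on either user-supplied files
(SAM + FASTA + BED + consensus FASTA) or a fresh simulation, writes all
result tables into one directory, and emits a machine-readable run report
(config echo, seed, versions, per-stage record counts) sufficient to
reproduce the run.  All outputs are plain text with deterministic row
order, so identical configuration and seed give byte-identical results.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .consensus import (
    ConsensusIndex,
    bisulfite_realign,
    profile_from_alignments,
    select_repeat_reads,
)
from .errors import ChipBsError
from .famstats import family_summary, moving_average_curve
from .io import read_bed, read_fasta, write_bedgraph
from .methdiff import (
    fraction_significant,
    score_region_methylation,
    test_element_methylation,
    test_methylation_windows,
)
from .methylation import (
    call_cytosines,
    calls_to_bedgraph_rows,
    estimate_conversion,
    parse_alignments,
)
from .occupancy import (
    attach_fdr,
    intersect_annotation,
    make_regions,
    scan_windows,
    score_elements,
    to_point_data,
)
from .simulate import SimConfig, build_toy_genome, simulate_reads, write_simulation

log = logging.getLogger("chipbs")


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    *,
    sim_config: SimConfig | None = None,
    chip_sam: str | Path | None = None,
    input_sam: str | Path | None = None,
    genome_fasta: str | Path | None = None,
    annotation_bed: str | Path | None = None,
    consensus_fasta: str | Path | None = None,
) -> dict[str, Path]:
    """Run every analysis stage; returns the map of output paths.

    Provide either ``sim_config`` (synthetic mode) or the four input file
    paths.  Raises :class:`ChipBsError` subclasses on contract violations
    (e.g. a missing spike-in contig aborts at the conversion estimate).
    """
    if not logging.getLogger().handlers and not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    report: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    paths: dict[str, Path] = {}

    if sim_config is not None:
        log.info("simulating synthetic experiment (seed %d)", sim_config.seed)
        genome, annotation, truth = build_toy_genome(sim_config)
        libraries = simulate_reads(sim_config, genome, annotation, truth)
        sim_dir = outdir / "sim"
        paths.update(write_simulation(sim_dir, sim_config, genome, annotation, truth, libraries))
        chip_sam = paths["chip_sam"]
        input_sam = paths["input_sam"]
        consensus_index = ConsensusIndex(
            {f: s for f, s in truth.consensi.items() if f != "tRNA-like"},
            spacer=config.consensus_spacer,
        )
        spike_contig = sim_config.spike_in_name
        report["sim_config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sim_config.__dict__.items()
        }
        report["stages"]["simulate"] = {
            lib: lr.n_reads for lib, lr in libraries.items()
        }
    else:
        missing = [
            name
            for name, val in (
                ("chip_sam", chip_sam),
                ("input_sam", input_sam),
                ("genome_fasta", genome_fasta),
                ("annotation_bed", annotation_bed),
                ("consensus_fasta", consensus_fasta),
            )
            if val is None
        ]
        if missing:
            raise ChipBsError(f"missing inputs (or use sim_config): {', '.join(missing)}")
        genome = read_fasta(genome_fasta)
        annotation = read_bed(annotation_bed)
        consensus_index = ConsensusIndex.from_fasta(consensus_fasta, spacer=config.consensus_spacer)
        spike_contig = config.spike_in_contig

    contig_lengths = {name: len(seq) for name, seq in genome.items()}

    # ---- methylation calling -------------------------------------------
    log.info("parsing alignments (cap %d placements)", config.genome_max_alignments)
    chip_records, chip_pstats = parse_alignments(chip_sam, config.genome_max_alignments)
    input_records, input_pstats = parse_alignments(input_sam, config.genome_max_alignments)
    report["stages"]["parse"] = {
        "chip": chip_pstats.__dict__,
        "input": input_pstats.__dict__,
    }

    log.info("calling cytosines")
    calls = {}
    for lib, records in (("chip", chip_records), ("input", input_records)):
        calls[lib] = call_cytosines(records, genome)
        paths[f"{lib}_calls"] = outdir / f"{lib}_calls.tsv"
        _float_csv(calls[lib], paths[f"{lib}_calls"])
        for which in ("fraction", "coverage"):
            p = outdir / f"{lib}_{which}.bedgraph"
            write_bedgraph(calls_to_bedgraph_rows(calls[lib], which), p)
            paths[f"{lib}_{which}_bedgraph"] = p

    conv = {
        lib: estimate_conversion(calls[lib], spike_contig) for lib in ("chip", "input")
    }
    paths["conversion"] = outdir / "conversion.tsv"
    pd.DataFrame(
        [
            (lib, c.converted_count, c.total_count, c.rate)
            for lib, c in conv.items()
        ],
        columns=["library", "converted", "total", "rate"],
    ).to_csv(paths["conversion"], sep="\t", index=False, float_format="%.6g")
    report["stages"]["conversion"] = {lib: conv[lib].rate for lib in conv}

    # ---- occupancy -----------------------------------------------------
    log.info("scanning %d bp windows (peak shift %d)", config.window_size, config.peak_shift)
    chip_pd = to_point_data(chip_records, config.peak_shift, contig_lengths)
    input_pd = to_point_data(input_records, config.peak_shift, contig_lengths)
    windows = scan_windows(
        chip_pd,
        input_pd,
        contig_lengths,
        config.window_size,
        config.step,
        exclude_contigs=(spike_contig,),
    )
    swapped = scan_windows(
        input_pd,
        chip_pd,
        contig_lengths,
        config.window_size,
        config.step,
        exclude_contigs=(spike_contig,),
    )
    windows = attach_fdr(windows, swapped)
    paths["windows"] = outdir / "windows.tsv"
    _float_csv(windows, paths["windows"])

    regions = make_regions(
        windows,
        config.q_threshold_regions,
        config.efdr_threshold,
        config.log2_threshold,
    )
    paths["regions"] = outdir / "regions.tsv"
    _float_csv(regions, paths["regions"])
    tallies, flagged = intersect_annotation(regions, annotation)
    paths["enriched_elements"] = outdir / "enriched_elements.tsv"
    _float_csv(flagged, paths["enriched_elements"])
    paths["enriched_class_counts"] = outdir / "enriched_class_counts.tsv"
    tallies.rename_axis("element_class").reset_index().to_csv(
        paths["enriched_class_counts"], sep="\t", index=False
    )
    element_scores = score_elements(
        annotation, chip_pd, input_pd, config.q_threshold_elements
    )
    paths["element_scores"] = outdir / "element_scores.tsv"
    _float_csv(element_scores, paths["element_scores"])
    report["stages"]["occupancy"] = {
        "n_windows": int(len(windows)),
        "n_regions": int(len(regions)),
        "n_enriched_elements": int(len(flagged)),
    }

    # ---- differential methylation --------------------------------------
    log.info("testing methylation windows (%d CpGs, min %d obs)", config.meth_window_cpgs, config.meth_min_obs)
    meth_windows = test_methylation_windows(
        calls["chip"],
        calls["input"],
        config.meth_window_cpgs,
        config.meth_min_obs,
        config.meth_fdr_threshold,
        config.meth_log2_threshold,
    )
    paths["meth_windows"] = outdir / "meth_windows.tsv"
    _float_csv(meth_windows, paths["meth_windows"])

    meth_scores = score_region_methylation(annotation, calls["input"])
    paths["percent_meth"] = outdir / "percent_meth.tsv"
    _float_csv(meth_scores, paths["percent_meth"])

    element_meth = test_element_methylation(
        annotation,
        calls["chip"],
        calls["input"],
        config.meth_min_obs,
        config.meth_fdr_threshold,
    )
    paths["element_meth_tests"] = outdir / "element_meth_tests.tsv"
    _float_csv(element_meth, paths["element_meth_tests"])
    frac_sig = fraction_significant(element_meth)
    paths["fraction_significant"] = outdir / "fraction_significant.tsv"
    _float_csv(frac_sig, paths["fraction_significant"])
    report["stages"]["methdiff"] = {
        "n_meth_windows": int(len(meth_windows)),
        "n_reported": int(meth_windows["reported"].sum()) if len(meth_windows) else 0,
    }

    # ---- consensus profiles --------------------------------------------
    log.info("realigning repeat reads to family consensi")
    profile_frames = []
    realign_report = {}
    for lib, records in (("chip", chip_records), ("input", input_records)):
        repeat_reads = select_repeat_reads(records, annotation, classes=("SINE",))
        alns, rstats = bisulfite_realign(
            repeat_reads,
            consensus_index,
            config.consensus_max_alignments,
            config.consensus_max_mismatch_frac,
        )
        profiles = profile_from_alignments(alns, consensus_index)
        for fam in sorted(profiles):
            frame = profiles[fam].to_frame()
            frame.insert(0, "library", lib)
            profile_frames.append(frame)
        realign_report[lib] = rstats.__dict__
    consensus_profiles = pd.concat(profile_frames, ignore_index=True)
    paths["consensus_profiles"] = outdir / "consensus_profiles.tsv"
    _float_csv(consensus_profiles, paths["consensus_profiles"])
    report["stages"]["consensus"] = realign_report

    # ---- family statistics ---------------------------------------------
    log.info("family-level statistics")
    comparison = family_summary(element_scores, meth_scores)
    paths["family_summary"] = outdir / "family_summary.tsv"
    _float_csv(comparison.summary, paths["family_summary"])
    kw_rows = []
    for axis, kw, dunn in (
        ("occupancy", comparison.kw_occupancy, comparison.dunn_occupancy),
        ("methylation", comparison.kw_methylation, comparison.dunn_methylation),
    ):
        if kw is None:
            continue
        kw_rows.append((axis, "KW", "", "", kw.H, kw.p_value))
        for r in dunn.table.itertuples():
            kw_rows.append((axis, "Dunn", r.group_a, r.group_b, r.z, r.p_adj))
    paths["family_tests"] = outdir / "family_tests.tsv"
    pd.DataFrame(
        kw_rows, columns=["axis", "test", "group_a", "group_b", "statistic", "p"]
    ).to_csv(paths["family_tests"], sep="\t", index=False, float_format="%.6g")
    if comparison.skipped_reason:
        report["stages"]["famstats"] = {"skipped": comparison.skipped_reason}

    scored = element_scores.merge(
        meth_scores[["element_id", "percent_meth", "covered"]], on="element_id"
    )
    scored = scored[scored["covered"] & scored["has_coverage"]]
    paths["moving_average"] = outdir / "moving_average.tsv"
    if len(scored) >= config.moving_average_block:
        curve = moving_average_curve(scored, config.moving_average_block)
        _float_csv(curve, paths["moving_average"])
    else:
        pd.DataFrame(columns=["mean_meth", "mean_occupancy"]).to_csv(
            paths["moving_average"], sep="\t", index=False
        )
        report["stages"]["moving_average"] = {
            "skipped": f"{len(scored)} scored elements < block {config.moving_average_block}"
        }

    paths["run_report"] = outdir / "run_report.json"
    paths["run_report"].write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    log.info("done: %d output files in %s", len(paths), outdir)
    return paths
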