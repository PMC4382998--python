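"""Shared fixtures: session-scoped synthetic experiments.

The heavier simulations are built once per session and reused by unit,
property and acceptance tests alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pytest

from chipbs.methylation import ReadAlignmentRecord, call_cytosines, parse_alignments
from chipbs.simulate import (
    SimConfig,
    SimTruth,
    build_toy_genome,
    simulate_reads,
    write_simulation,
)


@dataclass
class SimBundle:
    """A fully materialized synthetic experiment."""

    config: SimConfig
    genome: dict
    annotation: list
    truth: SimTruth
    libraries: dict
    paths: dict
    records: dict = field(default_factory=dict)  # library -> [ReadAlignmentRecord]
    parse_stats: dict = field(default_factory=dict)
    calls: dict = field(default_factory=dict)  # library -> calls DataFrame


def make_bundle(config: SimConfig, outdir, *, parse=True, call=True) -> SimBundle:
    genome, annotation, truth = build_toy_genome(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-depth libraries warn by contract
        libraries = simulate_reads(config, genome, annotation, truth)
    paths = write_simulation(outdir, config, genome, annotation, truth, libraries)
    bundle = SimBundle(config, genome, annotation, truth, libraries, paths)
    if parse:
        for lib, lr in libraries.items():
            if lr.n_reads == 0:
                continue
            recs, stats = parse_alignments(paths[f"{lib}_sam"], 7)
            bundle.records[lib] = recs
            bundle.parse_stats[lib] = stats
            if call:
                bundle.calls[lib] = call_cytosines(recs, genome)
    return bundle


@pytest.fixture(scope="session")
def null_sim(tmp_path_factory) -> SimBundle:
    """ChIP sampling independent of occupancy and methylation (fold = 1).

    Serves the null-calibration checks (occupancy windows, methylation
    type-I error) and the input-vs-ChIP consensus profile comparability.
    """
    cfg = SimConfig(
        genome_length=150_000,
        copies_per_family=50,
        n_trna_genes=10,
        occupancy_fold=1.0,
        n_occupied_loci=10,
        chip_depth=45_000,
        input_depth=45_000,
        conversion_rate=1.0,
        conversion_failure_rate=0.0,
        seed=11,
    )
    return make_bundle(cfg, tmp_path_factory.mktemp("null_sim"))


@pytest.fixture(scope="session")
def occupancy_sim(tmp_path_factory) -> SimBundle:
    """50 occupied loci at 8-fold enrichment among 300 elements."""
    cfg = SimConfig(
        genome_length=450_000,
        n_families=3,
        copies_per_family=94,
        n_trna_genes=18,
        n_occupied_loci=50,
        occupancy_fold=8.0,
        chip_depth=60_000,
        input_depth=60_000,
        seed=5,
    )
    return make_bundle(cfg, tmp_path_factory.mktemp("occ_sim"), call=False)


@pytest.fixture(scope="session")
def meth_recovery_sim(tmp_path_factory) -> SimBundle:
    """3 families x 100 copies at methylation levels 0.6 / 0.35 / 0.13, ~30x."""
    cfg = SimConfig(
        genome_length=160_000,
        n_families=3,
        copies_per_family=100,
        meth_prob_per_family=(0.6, 0.35, 0.13),
        n_trna_genes=0,
        chip_depth=0,
        input_depth=64_000,
        seed=7,
    )
    return make_bundle(cfg, tmp_path_factory.mktemp("meth_sim"))


@pytest.fixture(scope="session")
def conversion_sim(tmp_path_factory) -> SimBundle:
    """50,000 reads with 2% spike-in at conversion rate 0.995."""
    cfg = SimConfig(
        genome_length=100_000,
        copies_per_family=30,
        n_trna_genes=10,
        chip_depth=0,
        input_depth=50_000,
        conversion_rate=0.995,
        seed=13,
    )
    return make_bundle(cfg, tmp_path_factory.mktemp("conv_sim"))
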