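"""Generator correctness: structure, chemistry, determinism, truth tables."""

import numpy as np
import pandas as pd
import pytest

from chipbs.errors import SizingError
from chipbs.io import revcomp
from chipbs.simulate import SimConfig, build_toy_genome, simulate_reads

SMALL = dict(
    genome_length=40_000,
    copies_per_family=6,
    n_trna_genes=4,
    n_occupied_loci=5,
    chip_depth=2_000,
    input_depth=2_000,
)


def _element_seq(genome, el):
    seq = genome[el.contig][el.start : el.end]
    return seq if el.strand == "+" else revcomp(seq)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(conversion_rate=1.5),
        dict(spike_in_fraction=-0.1),
        dict(genome_length=0),
        dict(meth_prob_per_family=(0.5, 1.2, 0.1)),
        dict(fragment_len_mean=10, read_length=75),
        dict(occupancy_fold=0),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_zero_divergence_makes_identical_copies():
    cfg = SimConfig(**SMALL, family_divergence=0.0, trna_divergence=0.0, seed=4)
    genome, annotation, _ = build_toy_genome(cfg)
    for fam in {el.family for el in annotation}:
        seqs = {_element_seq(genome, el) for el in annotation if el.family == fam}
        assert len(seqs) == 1


def test_duplicate_pair_always_identical():
    cfg = SimConfig(**SMALL, family_divergence=0.08, seed=4)
    genome, annotation, _ = build_toy_genome(cfg)
    for fam in {el.family for el in annotation}:
        dups = [
            _element_seq(genome, el)
            for el in annotation
            if el.family == fam and int(el.element_id.rsplit("_", 1)[1]) < 2
        ]
        assert len(dups) == 2 and dups[0] == dups[1]


def test_zero_cpg_density_leaves_elements_cpg_free():
    cfg = SimConfig(**SMALL, cpg_density_per_family=0.0, cpg_density_trna=0.0, seed=4)
    _, annotation, truth = build_toy_genome(cfg)
    in_element = truth.cpg_table["element_id"] != ""
    assert not in_element.any()
    # and no CpG overlaps any element span either
    for el in annotation:
        inside = truth.cpg_table[
            (truth.cpg_table["pos"] >= el.start) & (truth.cpg_table["pos"] < el.end)
        ]
        inside = inside[inside["contig"] == el.contig]
        assert inside.empty


def test_annotation_row_count():
    cfg = SimConfig(**{**SMALL, "copies_per_family": 20, "n_trna_genes": 0}, n_families=3)
    _, annotation, _ = build_toy_genome(cfg)
    assert sum(el.element_class == "SINE" for el in annotation) == 60


def test_cpg_table_unique_per_strand():
    cfg = SimConfig(**SMALL, seed=9)
    genome, _, truth = build_toy_genome(cfg)
    assert not truth.cpg_table.duplicated(["contig", "pos", "strand"]).any()
    # every genomic CG appears on both strands
    for contig, seq in genome.items():
        n_cg = seq.count("CG")
        sub = truth.cpg_table[truth.cpg_table["contig"] == contig]
        assert len(sub) == 2 * n_cg


def test_sizing_error_names_deficit():
    cfg_kwargs = {**SMALL, "genome_length": 5_000}
    with pytest.raises(SizingError, match="deficit"):
        build_toy_genome(SimConfig(**cfg_kwargs))


def test_byte_identical_reproducibility():
    outs = []
    for _ in range(2):
        cfg = SimConfig(**SMALL, seed=21)
        genome, annotation, truth = build_toy_genome(cfg)
        libs = simulate_reads(cfg, genome, annotation, truth)
        outs.append((genome, libs["chip"].fastq, libs["chip"].sam, truth.cpg_table))
    assert outs[0][0] == outs[1][0]
    assert outs[0][1] == outs[1][1]
    assert outs[0][2] == outs[1][2]
    pd.testing.assert_frame_equal(outs[0][3], outs[1][3])


def test_complete_conversion_removes_every_c():
    cfg = SimConfig(
        **SMALL,
        conversion_rate=1.0,
        conversion_failure_rate=0.0,
        sequencing_error_rate=0.0,
        meth_prob_per_family=0.0,
        meth_prob_trna=0.0,
        meth_prob_background=0.0,
        meth_prob_concentration=None,
        seed=3,
    )
    genome, annotation, truth = build_toy_genome(cfg)
    libs = simulate_reads(cfg, genome, annotation, truth)
    ot = truth.read_origins[truth.read_origins["bisulfite_strand"] == "OT"]
    fastq = dict((rid, seq) for rid, seq, _ in libs["input"].fastq)
    checked = 0
    for rid in ot[ot["library"] == "input"]["read_id"]:
        assert "C" not in fastq[rid]
        checked += 1
    assert checked > 100


def test_complete_protection_retains_every_cpg_c():
    cfg = SimConfig(
        **SMALL,
        conversion_failure_rate=0.0,
        sequencing_error_rate=0.0,
        meth_prob_per_family=1.0,
        meth_prob_trna=1.0,
        meth_prob_background=1.0,
        meth_prob_concentration=None,
        seed=3,
    )
    genome, annotation, truth = build_toy_genome(cfg)
    libs = simulate_reads(cfg, genome, annotation, truth)
    garr = genome[cfg.genome_name]
    cpg_plus = {
        p
        for p, s, c in zip(
            truth.cpg_table["pos"], truth.cpg_table["strand"], truth.cpg_table["contig"]
        )
        if s == "+" and c == cfg.genome_name
    }
    checked = 0
    for qname, flag, contig, pos, *_rest in libs["input"].sam:
        seq = _rest[2]
        if flag != 0 or contig != cfg.genome_name:  # primary OT genome reads only
            continue
        for p in range(pos, pos + len(seq)):
            if p in cpg_plus:
                assert seq[p - pos] == "C"
                checked += 1
    assert checked > 200


def test_methylation_fraction_binomial_recovery():
    """Retained-C fraction at CpGs matches the Bernoulli rate within 3 SE."""
    cfg = SimConfig(
        **SMALL,
        conversion_rate=1.0,
        conversion_failure_rate=0.0,
        sequencing_error_rate=0.0,
        meth_prob_per_family=0.8,
        meth_prob_trna=0.8,
        meth_prob_background=0.8,
        meth_prob_concentration=None,
        seed=17,
    )
    genome, annotation, truth = build_toy_genome(cfg)
    libs = simulate_reads(cfg, genome, annotation, truth)
    cpg_plus = set(
        truth.cpg_table[
            (truth.cpg_table["strand"] == "+")
            & (truth.cpg_table["contig"] == cfg.genome_name)
        ]["pos"]
    )
    # independent oracle: direct counting on the emitted reads
    retained = converted = 0
    for qname, flag, contig, pos, _mq, _cig, seq, _q, _tags in libs["input"].sam:
        if flag != 0 or contig != cfg.genome_name:
            continue
        for p in range(pos, pos + len(seq)):
            if p in cpg_plus:
                if seq[p - pos] == "C":
                    retained += 1
                elif seq[p - pos] == "T":
                    converted += 1
    n = retained + converted
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(retained / n - 0.8) < 3 * se


def test_spike_in_fraction(conversion_sim):
    origins = conversion_sim.truth.read_origins
    frac = (origins["contig"] == conversion_sim.config.spike_in_name).mean()
    se = np.sqrt(0.02 * 0.98 / len(origins))
    assert abs(frac - 0.02) < 3 * se


def test_zero_depth_warns_and_is_empty():
    cfg = SimConfig(**{**SMALL, "chip_depth": 0})
    genome, annotation, truth = build_toy_genome(cfg)
    with pytest.warns(UserWarning, match="depth is zero"):
        libs = simulate_reads(cfg, genome, annotation, truth)
    assert libs["chip"].n_reads == 0
    assert libs["input"].n_reads == cfg.input_depth


def test_read_origin_conservation(null_sim):
    """Every emitted read appears exactly once in the origins table, and the
    truth SAM has one primary record per read."""
    for lib, lr in null_sim.libraries.items():
        origins = null_sim.truth.read_origins
        sub = origins[origins["library"] == lib]
        assert len(sub) == lr.n_reads
        assert not sub["read_id"].duplicated().any()
        primaries = [r for r in lr.sam if not (r[1] & 256)]
        assert len(primaries) == lr.n_reads


def test_duplicate_copies_emit_multimapping_reads(null_sim):
    origins = null_sim.truth.read_origins
    multi = origins[origins["n_valid_placements"] == 2]
    assert len(multi) > 0
    sam_ids = {}
    for lr in null_sim.libraries.values():
        for rec in lr.sam:
            sam_ids.setdefault(rec[0], []).append(rec)
    for rid in multi["read_id"].head(50):
        assert len(sam_ids[rid]) == 2


def test_enrichment_sanity(occupancy_sim):
    """The in-locus vs out-of-locus fragment-midpoint density ratio of ChIP
    over input approaches the configured fold enrichment."""
    cfg = occupancy_sim.config
    origins = occupancy_sim.truth.read_origins
    occupied = set(occupancy_sim.truth.occupied_loci["element_id"])
    spans = sorted(
        (el.start, el.end)
        for el in occupancy_sim.annotation
        if el.element_id in occupied
    )
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])

    def in_out(lib):
        sub = origins[
            (origins["library"] == lib) & (origins["contig"] == cfg.genome_name)
        ]
        mids = (sub["fragment_start"].to_numpy() + sub["fragment_end"].to_numpy()) // 2
        idx = np.searchsorted(starts, mids, side="right") - 1
        hit = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
        return hit.sum(), (~hit).sum()

    ci, co = in_out("chip")
    ii, io = in_out("input")
    double_ratio = (ci / ii) / (co / io)
    assert 0.85 * cfg.occupancy_fold < double_ratio < 1.15 * cfg.occupancy_fold
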