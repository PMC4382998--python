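"""Synthetic ChIP-bisulfite-seq data generator.

Builds a toy genome containing several SINE families of differing CpG
density and methylation level (an AluY-like young/high-methylation family
through an AluJ-like old/low-methylation family), tRNA-gene-like loci, and
an unmethylated spike-in contig emulating the lambda conversion control.
From it, ChIP and input libraries of bisulfite-converted single-end reads
are drawn: input fragments uniformly, ChIP fragments with probability mass
multiplied by a fold-enrichment over a chosen set of occupied loci.

Chemistry model
---------------
Each fragment is assigned an original-top (OT) or original-bottom (OB)
strand with probability 0.5.  On the converted strand every unmethylated C
reads as T with probability ``conversion_rate`` and every methylated C
reads as T with probability ``conversion_failure_rate``; the methylation
state of a CpG is drawn per molecule from its per-site truth probability.
Non-CpG cytosines are always unmethylated.  Sequencing errors are applied
after conversion.  Only substitution divergence between repeat copies is
simulated (no indels), and mutations never create novel CpGs — mirroring
the CpG erosion of aging repeats and keeping every element CpG mappable to
a consensus position.

Alignment is not simulated: a truth SAM records each read's true placement
and, for reads wholly contained in an exact-duplicate element pair, both
equally valid placements (or, in ``alignment_noise`` mode, one random
placement with the placement count in the NH tag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SizingError
from .io import AnnotatedElement, revcomp, write_bed, write_fasta, write_fastq, write_sam

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_DEFAULT_FAMILIES = ("AluY-like", "AluS-like", "AluJ-like")


def _family_names(n: int) -> list[str]:
    names = list(_DEFAULT_FAMILIES[:n])
    names += [f"fam{i + 1}-like" for i in range(len(names), n)]
    return names


def _broadcast(value, n: int, name: str) -> tuple:
    if np.isscalar(value):
        return tuple([value] * n)
    value = tuple(value)
    if len(value) > n:  # default 3-family tuples shrink with n_families
        return value[:n]
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or length {n}, got {len(value)}")
    return value


@dataclass
class SimConfig:
    """Parameters of one synthetic ChIP-BS-Seq experiment.

    Defaults emulate the published library characteristics: a 2% fully
    unmethylated spike-in, a bisulfite conversion rate of 99.87%, and SINE
    family methylation levels spanning the young-to-old Alu contrast.
    """

    genome_length: int = 200_000
    n_families: int = 3
    copies_per_family: int = 60
    family_divergence: float = 0.05
    cpg_density_per_family: float | Sequence[float] = (9.0, 7.0, 5.0)
    meth_prob_per_family: float | Sequence[float] = (0.6, 0.35, 0.13)
    element_length: int = 300
    n_trna_genes: int = 20
    trna_length: int = 80
    trna_divergence: float = 0.10
    cpg_density_trna: float = 3.0
    meth_prob_trna: float = 0.05
    cpg_density_background: float = 1.0
    meth_prob_background: float = 0.7
    meth_prob_concentration: float | None = 15.0
    n_occupied_loci: int = 50
    occupancy_fold: float = 8.0
    fragment_len_mean: float = 160.0
    fragment_len_sd: float = 30.0
    read_length: int = 75
    conversion_rate: float = 0.9987
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    spike_in_fraction: float = 0.02
    spike_in_length: int = 6_000
    spike_in_name: str = "spikein"
    genome_name: str = "chrsim"
    chip_depth: int = 50_000
    input_depth: int = 50_000
    alignment_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.cpg_density_per_family = _broadcast(
            self.cpg_density_per_family, self.n_families, "cpg_density_per_family"
        )
        self.meth_prob_per_family = _broadcast(
            self.meth_prob_per_family, self.n_families, "meth_prob_per_family"
        )
        for name in (
            "family_divergence",
            "trna_divergence",
            "conversion_rate",
            "conversion_failure_rate",
            "sequencing_error_rate",
            "spike_in_fraction",
            "meth_prob_background",
            "meth_prob_trna",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in self.meth_prob_per_family:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"meth_prob_per_family entries must be in [0, 1]")
        for name in (
            "genome_length",
            "n_families",
            "copies_per_family",
            "element_length",
            "read_length",
            "spike_in_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_trna_genes", "n_occupied_loci", "chip_depth", "input_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.occupancy_fold <= 0:
            raise ValueError("occupancy_fold must be positive")
        if self.fragment_len_mean < self.read_length:
            raise ValueError("fragment_len_mean must be >= read_length")


@dataclass
class SimTruth:
    """Ground truth emitted by the generator, for parameter-recovery tests."""

    cpg_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    occupied_loci: pd.DataFrame = field(default_factory=pd.DataFrame)
    read_origins: pd.DataFrame = field(default_factory=pd.DataFrame)
    consensi: dict[str, str] = field(default_factory=dict)
    # family -> {consensus position (C or G of a CpG): methylation probability}
    consensus_cpg_probs: dict[str, dict[int, float]] = field(default_factory=dict)


@dataclass
class LibraryReads:
    """One simulated library: FASTQ records, truth-SAM tuples, origin rows."""

    name: str
    fastq: list[tuple[str, str, str]]
    sam: list[tuple]
    origins: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return len(self.fastq)


# ---------------------------------------------------------------------------
# genome construction


def _random_seq_no_cpg(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random uint8 sequence with every CG dinucleotide broken (G -> A)."""
    seq = _BASES[rng.integers(0, 4, size=length)].copy()
    cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    seq[cg + 1] = ord("A")
    return seq


def _make_consensus(rng: np.random.Generator, length: int, cpg_per_100bp: float) -> np.ndarray:
    """Consensus with CpGs implanted on a random subset of even positions.

    The even-position grid guarantees implanted CpGs never overlap and that
    the consensus contains exactly the requested number of CpGs.
    """
    seq = _random_seq_no_cpg(rng, length)
    n_cpg = int(round(cpg_per_100bp * length / 100.0))
    n_slots = (length - 1) // 2
    if n_cpg > n_slots:
        raise ValueError(f"cannot place {n_cpg} CpGs in a {length} bp consensus")
    if n_cpg > 0:
        slots = rng.choice(n_slots, size=n_cpg, replace=False)
        pos = 2 * np.sort(slots)
        seq[pos] = ord("C")
        seq[pos + 1] = ord("G")
    return seq


def _gap_seq(rng: np.random.Generator, length: int, cpg_per_100bp: float) -> np.ndarray:
    """Background gap: fixed T...A frame (no boundary-spanning CpGs) with
    low-density CpGs implanted away from the ends."""
    seq = _random_seq_no_cpg(rng, length)
    seq[0] = ord("T")
    seq[-1] = ord("A")
    n_cpg = int(round(cpg_per_100bp * length / 100.0))
    n_slots = (length - 4) // 2  # implant at 2 + 2j, keep last two bases clear
    if n_cpg > 0 and n_slots > 0:
        slots = rng.choice(n_slots, size=min(n_cpg, n_slots), replace=False)
        pos = 2 + 2 * np.sort(slots)
        seq[pos] = ord("C")
        seq[pos + 1] = ord("G")
    return seq


def _mutate_copy(
    rng: np.random.Generator, consensus: np.ndarray, divergence: float
) -> np.ndarray:
    """Substitution-mutated copy; CpG-creating mutations are reverted."""
    copy = consensus.copy()
    if divergence > 0:
        hits = np.flatnonzero(rng.random(len(copy)) < divergence)
        if hits.size:
            shift = rng.integers(1, 4, size=hits.size)
            copy[hits] = _BASES[(_BASE_CODE[copy[hits]] + shift) % 4]
    # break any CG absent from the consensus (repeat copies erode CpGs,
    # they do not gain them; also keeps every element CpG consensus-mapped)
    cg = np.flatnonzero((copy[:-1] == ord("C")) & (copy[1:] == ord("G")))
    cons_cg = (consensus[:-1] == ord("C")) & (consensus[1:] == ord("G"))
    for i in cg:
        if not cons_cg[i]:
            copy[i + 1] = ord("A")
    return copy


def _draw_site_probs(
    rng: np.random.Generator, n: int, mean: float, concentration: float | None
) -> np.ndarray:
    """Per-CpG methylation probabilities: Beta around the family mean."""
    if concentration is None or concentration <= 0 or mean in (0.0, 1.0) or n == 0:
        return np.full(n, float(mean))
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=n)


def build_toy_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[AnnotatedElement], SimTruth]:
    """Assemble the toy genome, its annotation and the CpG truth table.

    Returns the reference (genome contig + spike-in contig), the element
    annotation, and a :class:`SimTruth` whose ``cpg_table`` lists every CpG
    cytosine on both strands with its methylation probability.  Copies 0
    and 1 of every family are exact duplicates, forcing multi-mapping.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()

    families = _family_names(config.n_families)
    consensi: dict[str, np.ndarray] = {}
    for fam, dens in zip(families, config.cpg_density_per_family):
        consensi[fam] = _make_consensus(rng, config.element_length, dens)
    trna_cons = _make_consensus(rng, config.trna_length, config.cpg_density_trna)

    # per-consensus-CpG methylation probabilities (shared by all copies)
    fam_meth = dict(zip(families, config.meth_prob_per_family))
    cons_probs: dict[str, dict[int, float]] = {}
    for fam in families:
        cpos = np.flatnonzero(
            (consensi[fam][:-1] == ord("C")) & (consensi[fam][1:] == ord("G"))
        )
        probs = _draw_site_probs(
            rng, cpos.size, fam_meth[fam], config.meth_prob_concentration
        )
        d: dict[int, float] = {}
        for p0, pr in zip(cpos, probs):
            d[int(p0)] = float(pr)  # top-strand C
            d[int(p0) + 1] = float(pr)  # bottom-strand C (the G position)
        cons_probs[fam] = d
    trna_cpos = np.flatnonzero((trna_cons[:-1] == ord("C")) & (trna_cons[1:] == ord("G")))
    trna_probs = _draw_site_probs(
        rng, trna_cpos.size, config.meth_prob_trna, config.meth_prob_concentration
    )
    cons_probs["tRNA-like"] = {}
    for p0, pr in zip(trna_cpos, trna_probs):
        cons_probs["tRNA-like"][int(p0)] = float(pr)
        cons_probs["tRNA-like"][int(p0) + 1] = float(pr)

    # element copies
    pieces: list[dict] = []
    for fam in families:
        for c in range(config.copies_per_family):
            seq = (
                consensi[fam].copy()
                if c < 2
                else _mutate_copy(rng, consensi[fam], config.family_divergence)
            )
            pieces.append(
                dict(
                    family=fam,
                    element_class="SINE",
                    copy=c,
                    seq=seq,
                    element_id=f"{fam.split('-')[0]}_{c:04d}",
                )
            )
    for c in range(config.n_trna_genes):
        seq = trna_cons.copy() if c < 2 else _mutate_copy(rng, trna_cons, config.trna_divergence)
        pieces.append(
            dict(
                family="tRNA-like",
                element_class="tRNA",
                copy=c,
                seq=seq,
                element_id=f"tRNA_{c:04d}",
            )
        )

    total_elem = sum(len(p["seq"]) for p in pieces)
    n_gaps = len(pieces) + 1
    background = config.genome_length - total_elem
    if background < 2 * n_gaps:
        raise SizingError(
            f"genome_length {config.genome_length} too small: elements need "
            f"{total_elem} bases plus {2 * n_gaps} of flanking background "
            f"(deficit {2 * n_gaps + total_elem - config.genome_length} bases)"
        )
    order = rng.permutation(len(pieces))
    # every gap gets a fixed T...A frame so no CpG can span an element boundary
    extra = rng.multinomial(background - 2 * n_gaps, np.full(n_gaps, 1.0 / n_gaps))
    strands = rng.choice(np.array(["+", "-"]), size=len(pieces))

    chunks: list[np.ndarray] = []
    annotation: list[AnnotatedElement] = []
    placed: list[dict] = []
    cursor = 0
    for slot, idx in enumerate(order):
        gap_len = 2 + int(extra[slot])
        chunks.append(_gap_seq(rng, gap_len, config.cpg_density_background))
        cursor += gap_len
        piece = pieces[idx]
        seq = piece["seq"]
        strand = strands[idx]
        if strand == "-":
            seq = np.frombuffer(revcomp(seq.tobytes().decode()).encode(), dtype=np.uint8)
        chunks.append(seq)
        start, end = cursor, cursor + len(seq)
        annotation.append(
            AnnotatedElement(
                contig=config.genome_name,
                start=start,
                end=end,
                strand=str(strand),
                element_id=piece["element_id"],
                family=piece["family"],
                element_class=piece["element_class"],
            )
        )
        placed.append(
            dict(
                start=start,
                end=end,
                strand=str(strand),
                family=piece["family"],
                copy=piece["copy"],
                element_id=piece["element_id"],
            )
        )
        cursor = end
    chunks.append(_gap_seq(rng, 2 + int(extra[-1]), config.cpg_density_background))
    genome_arr = np.concatenate(chunks)
    assert len(genome_arr) == config.genome_length

    spike_arr = _BASES[rng.integers(0, 4, size=config.spike_in_length)]

    genome = {
        config.genome_name: genome_arr.tobytes().decode(),
        config.spike_in_name: spike_arr.tobytes().decode(),
    }

    truth.consensi = {f: consensi[f].tobytes().decode() for f in families}
    truth.consensi["tRNA-like"] = trna_cons.tobytes().decode()
    truth.consensus_cpg_probs = cons_probs
    truth.cpg_table = _build_cpg_table(config, genome, placed, cons_probs)
    return genome, annotation, truth


def _build_cpg_table(
    config: SimConfig,
    genome: dict[str, str],
    placed: list[dict],
    cons_probs: dict[str, dict[int, float]],
) -> pd.DataFrame:
    """One row per CpG cytosine per strand, with its truth probability."""
    rows = []
    for contig, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if contig == config.spike_in_name:
            for i in cg:
                rows.append((contig, int(i), "+", 0.0, "", "", -1))
                rows.append((contig, int(i) + 1, "-", 0.0, "", "", -1))
            continue
        starts = np.array([p["start"] for p in placed])
        ends = np.array([p["end"] for p in placed])
        for i in cg:
            j = np.searchsorted(starts, i, side="right") - 1
            fam, eid, cons_c = "", "", -1
            prob = config.meth_prob_background
            if j >= 0 and i < ends[j] and i + 1 < ends[j]:
                p = placed[j]
                fam, eid = p["family"], p["element_id"]
                if p["strand"] == "+":
                    cons_c = int(i - p["start"])
                else:
                    # genome CG (i, i+1) maps to consensus CG whose C sits at
                    # end - 2 - i in consensus coordinates
                    cons_c = int(p["end"] - 2 - i)
                prob = cons_probs[fam].get(cons_c)
                if prob is None:  # pragma: no cover - construction forbids this
                    raise AssertionError("element CpG without consensus truth")
            rows.append((contig, int(i), "+", prob, fam, eid, cons_c))
            rows.append((contig, int(i) + 1, "-", prob, fam, eid, cons_c))
    df = pd.DataFrame(
        rows,
        columns=["contig", "pos", "strand", "meth_prob", "family", "element_id", "cons_pos"],
    )
    return df.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# read simulation

_ORIGIN_COLUMNS = [
    "read_id",
    "library",
    "contig",
    "pos",
    "fragment_start",
    "fragment_end",
    "strand",
    "bisulfite_strand",
    "n_valid_placements",
]


class _ContigModel:
    """Per-contig arrays used to convert reads quickly."""

    def __init__(self, seq: str, cpg: pd.DataFrame):
        self.arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.length = len(self.arr)
        probs_plus = {}
        probs_minus = {}
        for pos, strand, p in zip(cpg["pos"], cpg["strand"], cpg["meth_prob"]):
            (probs_plus if strand == "+" else probs_minus)[pos] = p
        cpos = np.flatnonzero(self.arr == ord("C"))
        gpos = np.flatnonzero(self.arr == ord("G"))
        self.c_plus = cpos
        self.p_plus = np.array([probs_plus.get(int(i), 0.0) for i in cpos])
        self.c_minus = gpos  # minus-strand Cs sit at plus-strand G positions
        self.p_minus = np.array([probs_minus.get(int(i), 0.0) for i in gpos])


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, minimum: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    for _ in range(60):
        bad = out < minimum
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(np.round(out).astype(int), minimum)


def _duplicate_pairs(annotation: Sequence[AnnotatedElement]) -> list[dict]:
    """Alternate-placement descriptors for the copy-0/copy-1 duplicate pairs."""
    by_family: dict[str, list[AnnotatedElement]] = {}
    for el in annotation:
        idx = int(el.element_id.rsplit("_", 1)[1])
        if idx < 2:
            by_family.setdefault(el.family, []).append(el)
    pairs = []
    for fam, els in by_family.items():
        if len(els) == 2:
            a, b = els
            pairs.append(dict(a=a, b=b, same_strand=a.strand == b.strand))
    return pairs


def simulate_reads(
    config: SimConfig,
    genome: dict[str, str],
    annotation: Sequence[AnnotatedElement],
    truth: SimTruth,
) -> dict[str, LibraryReads]:
    """Draw the ChIP and input libraries and fill in the remaining truth.

    Returns ``{"chip": LibraryReads, "input": LibraryReads}`` and populates
    ``truth.occupied_loci`` and ``truth.read_origins``.
    """
    rng = np.random.default_rng([config.seed, 20120715])
    gname, sname = config.genome_name, config.spike_in_name
    models = {
        name: _ContigModel(genome[name], truth.cpg_table[truth.cpg_table["contig"] == name])
        for name in (gname, sname)
    }

    n_elements = len(annotation)
    if config.n_occupied_loci > n_elements:
        raise SizingError(
            f"n_occupied_loci {config.n_occupied_loci} exceeds the "
            f"{n_elements} annotated elements"
        )
    occ_idx = rng.choice(n_elements, size=config.n_occupied_loci, replace=False)
    occupied = [annotation[i] for i in sorted(occ_idx)]
    truth.occupied_loci = pd.DataFrame(
        [(el.element_id, config.occupancy_fold) for el in occupied],
        columns=["element_id", "fold"],
    )

    glen = models[gname].length
    chip_w = np.ones(glen)
    for el in occupied:
        chip_w[el.start : el.end] = config.occupancy_fold
    chip_cum = np.cumsum(chip_w)

    dup_pairs = _duplicate_pairs(annotation)

    libraries: dict[str, LibraryReads] = {}
    all_origins = []
    for lib, depth in (("chip", config.chip_depth), ("input", config.input_depth)):
        if depth == 0:
            warnings.warn(f"{lib} depth is zero: emitting empty library")
            libraries[lib] = LibraryReads(lib, [], [], pd.DataFrame(columns=_ORIGIN_COLUMNS))
            continue
        lr = _simulate_library(
            rng, config, models, lib, depth, chip_cum if lib == "chip" else None, dup_pairs
        )
        libraries[lib] = lr
        all_origins.append(lr.origins)
    truth.read_origins = (
        pd.concat(all_origins, ignore_index=True) if all_origins else pd.DataFrame()
    )
    return libraries


def _simulate_library(
    rng: np.random.Generator,
    config: SimConfig,
    models: dict[str, _ContigModel],
    lib: str,
    depth: int,
    chip_cum: np.ndarray | None,
    dup_pairs: list[dict],
) -> LibraryReads:
    gname, sname = config.genome_name, config.spike_in_name
    gmodel, smodel = models[gname], models[sname]
    R = config.read_length

    spike_mask = rng.random(depth) < config.spike_in_fraction
    flen = _truncated_normal(
        rng, depth, config.fragment_len_mean, config.fragment_len_sd, R
    )
    is_ot = rng.random(depth) < 0.5

    # fragment midpoints: uniform for input/spike, fold-weighted for ChIP
    mids = np.empty(depth, dtype=np.int64)
    g = ~spike_mask
    if chip_cum is not None:
        u = rng.random(int(g.sum())) * chip_cum[-1]
        mids[g] = np.searchsorted(chip_cum, u)
    else:
        mids[g] = rng.integers(0, gmodel.length, size=int(g.sum()))
    mids[spike_mask] = rng.integers(0, smodel.length, size=int(spike_mask.sum()))

    contig_len = np.where(spike_mask, smodel.length, gmodel.length)
    flen = np.minimum(flen, contig_len)
    fstart = np.clip(mids - flen // 2, 0, contig_len - flen)
    fend = fstart + flen
    # single-end read interval: 5' read_length bases of the converted strand
    a = np.where(is_ot, fstart, fend - R)
    b = a + R

    # duplicate-pair membership (genome reads only, read fully inside a copy)
    alt = {}  # read index -> (alt_start, flip_strand)
    for pair in dup_pairs:
        for src, dst in ((pair["a"], pair["b"]), (pair["b"], pair["a"])):
            inside = g & (a >= src.start) & (b <= src.end)
            for i in np.flatnonzero(inside):
                off, ln = a[i] - src.start, b[i] - a[i]
                if pair["same_strand"]:
                    alt[int(i)] = (dst.start + off, False)
                else:
                    alt[int(i)] = (dst.end - off - ln, True)

    conv_r = config.conversion_rate
    fail_r = config.conversion_failure_rate
    err_r = config.sequencing_error_rate

    fastq: list[tuple[str, str, str]] = []
    sam: list[tuple] = []
    origins = []
    qual = "I" * R
    for i in range(depth):
        model = smodel if spike_mask[i] else gmodel
        contig = sname if spike_mask[i] else gname
        ai, bi = int(a[i]), int(b[i])
        seq = model.arr[ai:bi].copy()
        if is_ot[i]:
            lo = np.searchsorted(model.c_plus, ai)
            hi = np.searchsorted(model.c_plus, bi)
            sites = model.c_plus[lo:hi]
            probs = model.p_plus[lo:hi]
            tbase = ord("T")
        else:
            lo = np.searchsorted(model.c_minus, ai)
            hi = np.searchsorted(model.c_minus, bi)
            sites = model.c_minus[lo:hi]
            probs = model.p_minus[lo:hi]
            tbase = ord("A")  # C->T on the bottom strand is G->A in plus orientation
        if sites.size:
            meth = rng.random(sites.size) < probs
            u = rng.random(sites.size)
            converted = np.where(meth, u < fail_r, u < conv_r)
            seq[sites[converted] - ai] = tbase
        if err_r > 0:
            errs = np.flatnonzero(rng.random(R) < err_r)
            if errs.size:
                shift = rng.integers(1, 4, size=errs.size)
                seq[errs] = _BASES[(_BASE_CODE[seq[errs]] + shift) % 4]

        plus_seq = seq.tobytes().decode()
        rid = f"{lib}_{i:07d}"
        strand = "+" if is_ot[i] else "-"
        bs = "OT" if is_ot[i] else "OB"
        raw = plus_seq if is_ot[i] else revcomp(plus_seq)
        fastq.append((rid, raw, qual))

        placements = [(contig, ai, is_ot[i])]  # (contig, start, forward?)
        if int(i) in alt:
            alt_start, flip = alt[int(i)]
            placements.append((contig, int(alt_start), is_ot[i] != flip))
        k = len(placements)
        if config.alignment_noise and k > 1:
            keep = int(rng.integers(0, k))
            placements = [placements[keep]]
        mapq = 60 if k == 1 else 3
        for j, (pc, ps, fwd) in enumerate(placements):
            flag = (0 if fwd else 16) | (0 if j == 0 else 256)
            pseq = plus_seq if fwd == is_ot[i] else revcomp(plus_seq)
            sam.append(
                (
                    rid,
                    flag,
                    pc,
                    ps,
                    mapq,
                    f"{R}M",
                    pseq,
                    qual,
                    [f"NH:i:{k}", "XB:Z:" + ("OT" if fwd else "OB")],
                )
            )
        origins.append(
            (rid, lib, contig, ai, int(fstart[i]), int(fend[i]), strand, bs, k)
        )

    odf = pd.DataFrame(origins, columns=_ORIGIN_COLUMNS)
    return LibraryReads(lib, fastq, sam, odf)


# ---------------------------------------------------------------------------
# output


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    genome: dict[str, str],
    annotation: Sequence[AnnotatedElement],
    truth: SimTruth,
    libraries: dict[str, LibraryReads],
) -> dict[str, Path]:
    """Write every simulation artifact to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["consensus"] = outdir / "consensus.fa"
    write_fasta(
        {f: s for f, s in truth.consensi.items() if f != "tRNA-like"}, paths["consensus"]
    )
    paths["annotation"] = outdir / "annotation.bed"
    write_bed(annotation, paths["annotation"])
    for lib, lr in libraries.items():
        paths[f"{lib}_fastq"] = outdir / f"{lib}.fastq"
        write_fastq(lr.fastq, paths[f"{lib}_fastq"])
        paths[f"{lib}_sam"] = outdir / f"{lib}.sam"
        write_sam(lr.sam, contig_lengths, paths[f"{lib}_sam"])
    for name, df in (
        ("truth_cpg", truth.cpg_table),
        ("truth_occupied", truth.occupied_loci),
        ("truth_origins", truth.read_origins),
    ):
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    return paths
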