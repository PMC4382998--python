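"""Per-cytosine methylation calling from bisulfite alignments.

Reads are taken from SAM including secondary alignments.  A read with
1 < k <= ``max_alignments`` placements contributes one record per
placement, each down-weighted to 1/k so that repeat reads are included
without inflating coverage; reads exceeding the cap are dropped (and
counted).  At every covered reference cytosine a retained C (OT reads) or
G (OB reads, plus-strand orientation) adds to the weighted methylated
count, a converted T / A to the unmethylated count, and any other base —
a sequencing error or SNP — is ignored.  The bisulfite conversion rate is
estimated from the unmethylated spike-in contig as the fraction of its
cytosine observations that read converted, across all contexts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NoConversionControlError, ParseError
from .io import open_sam

CALL_COLUMNS = ["contig", "pos", "strand", "context", "meth", "unmeth"]


@dataclass
class ReadAlignmentRecord:
    """One placement of one read, with its multi-mapper weight = 1/k."""

    read_id: str
    contig: str
    start: int
    strand: str  # mapping strand, +/-
    bisulfite_strand: str  # OT / OB
    sequence: str  # plus-strand orientation
    n_alignments: int
    weight: float


@dataclass
class ParseStats:
    n_reads: int = 0
    n_kept: int = 0
    n_dropped_overcap: int = 0
    n_unmapped: int = 0
    n_skipped_cigar: int = 0


@dataclass
class ConversionEstimate:
    """Spike-in bisulfite conversion rate: converted / total observations."""

    converted_count: float
    total_count: float

    @property
    def rate(self) -> float:
        return self.converted_count / self.total_count


def parse_alignments(
    sam_path: str | Path,
    max_alignments: int = 7,
    *,
    uniform_weights: bool = False,
) -> tuple[list[ReadAlignmentRecord], ParseStats]:
    """Read a SAM file into weighted alignment records.

    Placements of one read are grouped by query name; k is taken from the
    NH tag when present, otherwise from the number of mapped records.
    ``uniform_weights`` gives every placement weight 1 instead of 1/k
    (sensitivity analysis).
    """
    groups: dict[str, list] = {}
    stats = ParseStats()
    with open_sam(sam_path) as fh:
        try:
            for aln in fh:
                if aln.is_unmapped:
                    stats.n_unmapped += 1
                    continue
                groups.setdefault(aln.query_name, []).append(
                    (
                        fh.get_reference_name(aln.reference_id),
                        aln.reference_start,
                        aln.is_reverse,
                        aln.query_sequence,
                        aln.cigartuples,
                        aln.get_tag("NH") if aln.has_tag("NH") else None,
                        aln.get_tag("XB") if aln.has_tag("XB") else None,
                    )
                )
            # pysam raises on truncated/malformed records during iteration
        except (ValueError, OSError) as exc:
            raise ParseError(f"malformed SAM record: {exc}", str(sam_path)) from exc

    records: list[ReadAlignmentRecord] = []
    for qname in groups:
        placements = groups[qname]
        stats.n_reads += 1
        nh = next((p[5] for p in placements if p[5] is not None), None)
        k = int(nh) if nh is not None else len(placements)
        k = max(k, len(placements))
        if k > max_alignments:
            stats.n_dropped_overcap += 1
            continue
        stats.n_kept += 1
        w = 1.0 if uniform_weights else 1.0 / k
        for contig, start, is_rev, seq, cigar, _, xb in placements:
            if cigar is None or any(op != 0 for op, _ in cigar):
                # only ungapped (all-M) records are call-able here
                stats.n_skipped_cigar += 1
                continue
            bs = xb if xb in ("OT", "OB") else ("OB" if is_rev else "OT")
            records.append(
                ReadAlignmentRecord(
                    read_id=qname,
                    contig=contig,
                    start=start,
                    strand="-" if is_rev else "+",
                    bisulfite_strand=bs,
                    sequence=seq,
                    n_alignments=k,
                    weight=w,
                )
            )
    return records, stats


def _context_tables(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position CpG/CHG/CHH context codes for plus (C) and minus (G) strands."""
    L = len(ref)
    is_c = ref == ord("C")
    is_g = ref == ord("G")
    ctx_plus = np.full(L, 2, dtype=np.int8)  # 0=CpG 1=CHG 2=CHH
    nxt = np.zeros(L, dtype=bool)
    nxt[:-1] = is_g[1:]
    ctx_plus[nxt] = 0
    nxt2 = np.zeros(L, dtype=bool)
    nxt2[:-2] = is_g[2:] & ~is_g[1:-1]
    ctx_plus[nxt2 & (ctx_plus != 0)] = 1
    ctx_minus = np.full(L, 2, dtype=np.int8)
    prv = np.zeros(L, dtype=bool)
    prv[1:] = is_c[:-1]
    ctx_minus[prv] = 0
    prv2 = np.zeros(L, dtype=bool)
    prv2[2:] = is_c[:-2] & ~is_c[1:-1]
    ctx_minus[prv2 & (ctx_minus != 0)] = 1
    return ctx_plus, ctx_minus


_CTX_NAMES = np.array(["CpG", "CHG", "CHH"])


def call_cytosines(
    records: Iterable[ReadAlignmentRecord],
    reference: dict[str, str],
) -> pd.DataFrame:
    """Accumulate weighted methylated/unmethylated counts per cytosine.

    Returns a table with one row per covered cytosine: contig, 0-based
    position of the C on its own strand (minus-strand Cs are reported at
    the plus-strand coordinate of the G), strand, context, and the
    weighted ``meth`` / ``unmeth`` counts.
    """
    refs = {name: np.frombuffer(seq.encode(), dtype=np.uint8) for name, seq in reference.items()}
    acc: dict[str, list[np.ndarray]] = {}
    n_out_of_bounds = 0
    for name, arr in refs.items():
        L = len(arr)
        acc[name] = [np.zeros(L) for _ in range(4)]  # meth+, unmeth+, meth-, unmeth-

    for rec in records:
        arr = refs.get(rec.contig)
        if arr is None:
            raise KeyError(f"record contig {rec.contig!r} absent from reference")
        seq = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        start, end = rec.start, rec.start + len(seq)
        if start < 0 or end > len(arr):
            n_out_of_bounds += 1
            continue
        ref_slice = arr[start:end]
        mp, up, mm, um = acc[rec.contig]
        if rec.bisulfite_strand == "OT":
            cs = ref_slice == ord("C")
            np.add.at(mp, start + np.flatnonzero(cs & (seq == ord("C"))), rec.weight)
            np.add.at(up, start + np.flatnonzero(cs & (seq == ord("T"))), rec.weight)
        else:
            gs = ref_slice == ord("G")
            np.add.at(mm, start + np.flatnonzero(gs & (seq == ord("G"))), rec.weight)
            np.add.at(um, start + np.flatnonzero(gs & (seq == ord("A"))), rec.weight)

    if n_out_of_bounds:
        warnings.warn(f"{n_out_of_bounds} records extended past a contig end; skipped")

    frames = []
    for name, arr in refs.items():
        mp, up, mm, um = acc[name]
        ctx_plus, ctx_minus = _context_tables(arr)
        for strand, (m, u, ctx) in (
            ("+", (mp, up, ctx_plus)),
            ("-", (mm, um, ctx_minus)),
        ):
            covered = np.flatnonzero((m > 0) | (u > 0))
            if covered.size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "contig": name,
                        "pos": covered,
                        "strand": strand,
                        "context": _CTX_NAMES[ctx[covered]],
                        "meth": m[covered],
                        "unmeth": u[covered],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)


def pool_cpg_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each symmetric CpG onto the plus-strand C.

    Optional: the default analysis keeps per-C calls (consensus profiles
    are per-C).  Minus-strand CpG counts at position p are added to the
    plus-strand call at p - 1.
    """
    cpg = calls[calls["context"] == "CpG"].copy()
    other = calls[calls["context"] != "CpG"]
    minus = cpg["strand"] == "-"
    cpg.loc[minus, "pos"] = cpg.loc[minus, "pos"] - 1
    cpg["strand"] = "+"
    pooled = (
        cpg.groupby(["contig", "pos", "strand", "context"], as_index=False)[["meth", "unmeth"]]
        .sum()
    )
    out = pd.concat([pooled, other], ignore_index=True)
    return out.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)


def estimate_conversion(calls: pd.DataFrame, spike_contig: str) -> ConversionEstimate:
    """Conversion rate from the unmethylated spike-in: unmeth / total.

    Uses every cytosine context on the spike-in contig, since all of its
    cytosines are unmethylated by construction.
    """
    spike = calls[calls["contig"] == spike_contig]
    total = float(spike["meth"].sum() + spike["unmeth"].sum())
    if spike.empty or total <= 0:
        raise NoConversionControlError(
            f"no conversion control: zero coverage on spike-in contig {spike_contig!r}"
        )
    return ConversionEstimate(converted_count=float(spike["unmeth"].sum()), total_count=total)


def calls_to_bedgraph_rows(
    calls: pd.DataFrame, which: str = "fraction"
) -> list[tuple[str, int, int, float]]:
    """bedGraph rows (contig, start, end, value) for fraction or coverage."""
    rows = []
    for contig, pos, meth, unmeth in zip(
        calls["contig"], calls["pos"], calls["meth"], calls["unmeth"]
    ):
        cov = meth + unmeth
        value = cov if which == "coverage" else (meth / cov if cov > 0 else 0.0)
        rows.append((contig, int(pos), int(pos) + 1, float(value)))
    return rows
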