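"""File formats and shared records.

Everything on disk is plain text: FASTA, FASTQ, SAM, BED6+2 (name column =
element id, two extra columns = repeat family and element class), bedGraph
and tab-separated statistics tables.  Internally all coordinates are
0-based half-open; the 1-based conversion happens exactly once, at the SAM
and bedGraph boundaries where those formats demand it (SAM POS is 1-based,
bedGraph is 0-based half-open like BED).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .errors import ParseError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotatedElement:
    """A genomic interval tagged with repeat family and class.

    ``element_class`` is one of ``SINE``, ``tRNA`` or ``other``; family is
    the repeat (sub)family label, e.g. ``AluY-like``.
    """

    contig: str
    start: int
    end: int
    strand: str
    element_id: str
    family: str
    element_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval for {self.element_id}")
        if self.element_class == "SINE" and not self.family:
            raise ValueError(f"SINE element {self.element_id} lacks a family")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict.

    The name is the first whitespace-separated token of the header
    (Repbase-style headers carry the family name there).
    """
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else None
                if not name:
                    raise ParseError("empty FASTA header", str(path), lineno)
                chunks = []
            else:
                if name is None:
                    raise ParseError("sequence before first header", str(path), lineno)
                chunks.append(line.strip().upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) triplets."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError("malformed FASTQ record", str(path))
            yield header[1:].split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED6+2 annotation


_BED_COLUMNS = ["contig", "start", "end", "element_id", "score", "strand", "family", "element_class"]


def read_bed(path: str | Path) -> list[AnnotatedElement]:
    """Read a BED6+2 annotation (columns 7-8 = family, class)."""
    elements: list[AnnotatedElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError(
                    f"expected 8 BED6+2 columns, got {len(parts)}", str(path), lineno
                )
            try:
                elements.append(
                    AnnotatedElement(
                        contig=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        element_id=parts[3],
                        strand=parts[5],
                        family=parts[6],
                        element_class=parts[7],
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), str(path), lineno) from exc
    return elements


def write_bed(elements: Sequence[AnnotatedElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in sorted(elements, key=lambda e: (e.contig, e.start, e.end)):
            fh.write(
                "\t".join(
                    [
                        el.contig,
                        str(el.start),
                        str(el.end),
                        el.element_id,
                        "0",
                        el.strand,
                        el.family,
                        el.element_class,
                    ]
                )
                + "\n"
            )


def elements_to_frame(elements: Sequence[AnnotatedElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.contig, e.start, e.end, e.strand, e.element_id, e.family, e.element_class)
            for e in elements
        ],
        columns=["contig", "start", "end", "strand", "element_id", "family", "element_class"],
    )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | Path, *, precision: int = 6
) -> None:
    """Write sorted, non-overlapping (contig, start, end, value) rows."""
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    prev: tuple[str, int] | None = None
    with open(path, "w") as fh:
        for contig, start, end, value in rows:
            if prev is not None and prev[0] == contig and start < prev[1]:
                raise ValueError("overlapping bedGraph intervals")
            prev = (contig, end)
            fh.write(f"{contig}\t{start}\t{end}\t{value:.{precision}g}\n")


# ---------------------------------------------------------------------------
# SAM

SamTuple = tuple  # (qname, flag, contig, pos0, mapq, cigar, seq, qual, tags)


def write_sam(
    records: Iterable[SamTuple],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write SAM text. ``pos0`` in each record tuple is 0-based; POS is
    emitted 1-based. ``tags`` is a list of pre-formatted tag strings."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write("@PG\tID:chipbs\tPN:chipbs\n")
        for qname, flag, contig, pos0, mapq, cigar, seq, qual, tags in records:
            fields = [
                qname,
                str(flag),
                contig,
                str(pos0 + 1),
                str(mapq),
                cigar,
                "*",
                "0",
                "0",
                seq,
                qual,
                *tags,
            ]
            fh.write("\t".join(fields) + "\n")


def open_sam(path: str | Path) -> pysam.AlignmentFile:
    """Open a SAM file for reading, demanding a sequence header."""
    try:
        fh = pysam.AlignmentFile(str(path), "r")
    except ValueError as exc:
        raise ParseError(f"cannot parse SAM: {exc}", str(path)) from exc
    if not fh.header.references:
        fh.close()
        raise ParseError("SAM file has no @SQ header lines", str(path))
    return fh
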