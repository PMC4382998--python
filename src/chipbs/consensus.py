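"""Repeat-family consensus realignment and per-base methylation profiles.

Reads intersecting annotated repeats are realigned, ungapped, against each
family consensus in collapsed bisulfite space: an original-top read is
compared C->T-collapsed against the C->T-collapsed consensus, and an
original-bottom read is reverse-complemented and compared G->A-collapsed
(both chemistries and both orientations are always tried, so the caller
needs no strand information).  All placements within one mismatch of a
read's best placement are reported, up to a cap (default 14); a read's
weight, 1/k over its reported placements, then accumulates into per-family
per-position methylated/unmethylated counts at every consensus C (top
strand) or G (bottom-strand C), yielding the fraction-methylated
meta-profile of each family on consensus coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import overlaps
from .io import AnnotatedElement, read_fasta, revcomp
from .methylation import ReadAlignmentRecord


def _collapse_ct(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("C")] = ord("T")
    return out


def _collapse_ga(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("G")] = ord("A")
    return out


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


@dataclass
class ConsensusIndex:
    """Family consensus sequences with cached collapsed forms.

    Mirrors a concatenated consensus index with N spacers between entries;
    the concatenation (see :meth:`concatenated`) is an internal detail and
    never appears in output coordinates, which are per-family.
    """

    consensi: dict[str, str]
    spacer: int = 100
    _ct: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ga: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _raw: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for fam, seq in self.consensi.items():
            if "N" in seq.upper():
                raise ValueError(f"consensus {fam!r} contains N")
            arr = _to_arr(seq)
            self._raw[fam] = arr
            self._ct[fam] = _collapse_ct(arr)
            self._ga[fam] = _collapse_ga(arr)

    @classmethod
    def from_fasta(cls, path: str | Path, spacer: int = 100) -> "ConsensusIndex":
        return cls(consensi=read_fasta(path), spacer=spacer)

    def concatenated(self) -> str:
        """All consensi joined with spacer-length runs of N."""
        return ("N" * self.spacer).join(self.consensi[f] for f in self.consensi)


@dataclass
class ConsensusAlignment:
    """One reported placement of one read on one family consensus."""

    read_id: str
    family: str
    offset: int  # 0-based consensus start
    mode: str  # "CT" (top-strand chemistry) or "GA" (bottom-strand)
    mismatches: int
    weight: float
    oriented_seq: str  # original bases, oriented to the consensus


@dataclass
class RealignStats:
    n_reads: int = 0
    n_aligned: int = 0
    n_unplaced: int = 0
    n_dropped_overcap: int = 0
    n_too_long: int = 0


def select_repeat_reads(
    records: Iterable[ReadAlignmentRecord],
    annotation: Sequence[AnnotatedElement],
    classes: Sequence[str] = ("SINE",),
) -> list[tuple[str, str]]:
    """Reads with >= 1 bp overlap between any placement and a class element.

    Returns (read_id, raw sequence) pairs, each read once; the sequence is
    taken from the read's first encountered placement (orientation is
    irrelevant downstream, since realignment tries both).
    """
    wanted = [el for el in annotation if el.element_class in classes]
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for el in wanted:
        by_contig.setdefault(el.contig, []).append((el.start, el.end))
    kept: dict[str, str] = {}
    for rec in records:
        if rec.read_id in kept:
            continue
        ivs = by_contig.get(rec.contig, ())
        start, end = rec.start, rec.start + len(rec.sequence)
        if any(overlaps(start, end, s, e) for s, e in ivs):
            kept[rec.read_id] = rec.sequence
    return list(kept.items())


def bisulfite_realign(
    reads: Iterable[tuple[str, str]],
    index: ConsensusIndex,
    max_alignments: int = 14,
    max_mismatch_frac: float = 0.2,
) -> tuple[list[ConsensusAlignment], RealignStats]:
    """Ungapped all-placements realignment in collapsed bisulfite space.

    A placement is valid when its collapsed-space mismatch count is at
    most ``max_mismatch_frac`` of the read length; placements within one
    mismatch of the read's best are reported (up to ``max_alignments``,
    beyond which the read is dropped) with weight 1/k each.
    """
    families = list(index.consensi)
    stats = RealignStats()
    out: list[ConsensusAlignment] = []
    for read_id, seq in reads:
        stats.n_reads += 1
        r = _to_arr(seq)
        rc = _to_arr(revcomp(seq))
        # both chemistries x both orientations: raw top-strand reads match
        # CT as-is, raw bottom-strand reads match GA after revcomp, and
        # reads supplied in reference orientation match the other two.
        modes = (
            ("CT", _collapse_ct(r), seq),
            ("GA", _collapse_ga(rc), revcomp(seq)),
            ("CT", _collapse_ct(rc), revcomp(seq)),
            ("GA", _collapse_ga(r), seq),
        )
        hits: list[tuple[int, str, int, str, str]] = []  # (mm, family, offset, mode, oriented)
        too_long_everywhere = True
        max_mm = int(max_mismatch_frac * len(r))
        for fam in families:
            for mode, collapsed_read, oriented in modes:
                cons = index._ct[fam] if mode == "CT" else index._ga[fam]
                if len(r) > len(cons):
                    continue
                too_long_everywhere = False
                windows = np.lib.stride_tricks.sliding_window_view(cons, len(r))
                mm = (windows != collapsed_read).sum(axis=1)
                for off in np.flatnonzero(mm <= max_mm):
                    hits.append((int(mm[off]), fam, int(off), mode, oriented))
        if too_long_everywhere:
            stats.n_too_long += 1
            continue
        if not hits:
            stats.n_unplaced += 1
            continue
        best = min(h[0] for h in hits)
        near = [h for h in hits if h[0] <= best + 1]
        if len(near) > max_alignments:
            stats.n_dropped_overcap += 1
            continue
        stats.n_aligned += 1
        w = 1.0 / len(near)
        for mm_count, fam, off, mode, oriented in near:
            out.append(
                ConsensusAlignment(
                    read_id=read_id,
                    family=fam,
                    offset=off,
                    mode=mode,
                    mismatches=mm_count,
                    weight=w,
                    oriented_seq=oriented,
                )
            )
    return out, stats


@dataclass
class ConsensusProfile:
    """Per-position methylation counts on one family's consensus."""

    family: str
    meth: np.ndarray
    unmeth: np.ndarray

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def fraction(self) -> np.ndarray:
        """Fraction methylated; NaN where there is no coverage."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth / cov, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "pos": np.arange(len(self.meth)),
                "meth": self.meth,
                "unmeth": self.unmeth,
                "fraction": self.fraction,
            }
        )


def profile_from_alignments(
    alignments: Iterable[ConsensusAlignment], index: ConsensusIndex
) -> dict[str, ConsensusProfile]:
    """Accumulate per-position methylation profiles from realignments.

    CT-mode placements are read at consensus C positions (read base C =
    methylated, T = unmethylated); GA-mode placements at consensus G
    positions (G = methylated, A = unmethylated); other bases are ignored.
    """
    profiles = {
        fam: ConsensusProfile(fam, np.zeros(len(s)), np.zeros(len(s)))
        for fam, s in index.consensi.items()
    }
    for aln in alignments:
        cons = index._raw[aln.family]
        prof = profiles[aln.family]
        seq = _to_arr(aln.oriented_seq)
        lo, hi = aln.offset, aln.offset + len(seq)
        ref_slice = cons[lo:hi]
        if aln.mode == "CT":
            sites = ref_slice == ord("C")
            np.add.at(prof.meth, lo + np.flatnonzero(sites & (seq == ord("C"))), aln.weight)
            np.add.at(prof.unmeth, lo + np.flatnonzero(sites & (seq == ord("T"))), aln.weight)
        else:
            sites = ref_slice == ord("G")
            np.add.at(prof.meth, lo + np.flatnonzero(sites & (seq == ord("G"))), aln.weight)
            np.add.at(prof.unmeth, lo + np.flatnonzero(sites & (seq == ord("A"))), aln.weight)
    return profiles
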