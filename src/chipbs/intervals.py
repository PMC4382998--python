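"""Interval arithmetic.

All coordinates in the package are 0-based half-open [start, end); SAM input
and output is converted to/from 1-based exactly once at the file boundary.
Under this convention two intervals that merely touch (a.end == b.start) do
NOT overlap.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Number of bases shared by [a_start, a_end) and [b_start, b_end)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return overlap_length(a_start, a_end, b_start, b_end) > 0


def merge_intervals(
    intervals: Iterable[tuple[int, int]], *, join_adjacent: bool = True
) -> list[tuple[int, int]]:
    """Union of intervals; adjacent (touching) intervals are joined by default."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (join_adjacent and s == out[-1][1])):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def find_overlapping(
    query_start: int,
    query_end: int,
    starts: Sequence[int],
    ends: Sequence[int],
) -> list[int]:
    """Indices i with overlap between the query and [starts[i], ends[i]).

    ``starts``/``ends`` need not be sorted; linear scan (element tables in
    this package are small).
    """
    return [
        i
        for i, (s, e) in enumerate(zip(starts, ends))
        if overlaps(query_start, query_end, s, e)
    ]
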