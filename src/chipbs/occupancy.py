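"""Sliding-window occupancy calling of ChIP vs input point data.

Alignments are first reduced to single-position point data: each record
contributes one point, shifted by half the peak shift (default 116 bp)
toward its fragment midpoint.  Fixed-width windows (default 300 bp,
tiled at half-window steps) are then tested for ChIP enrichment with a
one-sided binomial test under the library-size null, and every window
receives two phred-scaled false-discovery statistics: a Benjamini-Hochberg
Q-value across all tested windows and an empirical FDR obtained by
re-scanning with the ChIP and input labels swapped.  Windows passing the
configured Q-value / empirical-FDR / log2-ratio thresholds (defaults 20,
13, 1) are merged into enriched regions, regions are intersected with the
element annotation, and every annotated element is additionally scored
over its own span (the per-element Q-value threshold default is 70).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io import AnnotatedElement
from .methylation import ReadAlignmentRecord

PHRED_CAP = 100.0

WINDOW_COLUMNS = [
    "contig",
    "start",
    "end",
    "chip_sum",
    "input_sum",
    "log2_ratio",
    "p_value",
]


@dataclass
class PointData:
    """Shifted read positions and weights for one library, per contig."""

    positions: dict[str, np.ndarray]  # sorted int positions
    weights: dict[str, np.ndarray]  # aligned with positions
    library_size: float

    @classmethod
    def from_records(
        cls,
        records: Iterable[ReadAlignmentRecord],
        peak_shift: int,
        contig_lengths: dict[str, int],
    ) -> "PointData":
        return to_point_data(records, peak_shift, contig_lengths)

    def window_sums(self, contig: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Total point weight in [start, end) for each window, via prefix sums."""
        pos = self.positions.get(contig)
        if pos is None or pos.size == 0:
            return np.zeros(len(starts))
        csum = np.concatenate([[0.0], np.cumsum(self.weights[contig])])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        return csum[hi] - csum[lo]


def to_point_data(
    records: Iterable[ReadAlignmentRecord],
    peak_shift: int,
    contig_lengths: dict[str, int],
) -> PointData:
    """Reduce records to fragment-midpoint point data.

    A plus-strand record at start s becomes a point at s + peak_shift/2;
    a minus-strand record ending at e becomes a point at e - peak_shift/2.
    Points are clipped to contig bounds and keep the record weight.
    """
    half = peak_shift // 2
    pts: dict[str, list] = {c: [] for c in contig_lengths}
    wts: dict[str, list] = {c: [] for c in contig_lengths}
    total = 0.0
    for rec in records:
        if rec.strand == "+":
            p = rec.start + half
        else:
            p = rec.start + len(rec.sequence) - half
        L = contig_lengths[rec.contig]
        p = min(max(int(p), 0), L - 1)
        pts[rec.contig].append(p)
        wts[rec.contig].append(rec.weight)
        total += rec.weight
    positions: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for contig in contig_lengths:
        p = np.asarray(pts[contig], dtype=np.int64)
        w = np.asarray(wts[contig], dtype=float)
        order = np.argsort(p, kind="stable")
        positions[contig] = p[order]
        weights[contig] = w[order]
    return PointData(positions=positions, weights=weights, library_size=total)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def scan_windows(
    chip: PointData,
    input_: PointData,
    contig_lengths: dict[str, int],
    window_size: int = 300,
    step: int | None = None,
    *,
    exclude_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Tile every contig with fixed windows and test ChIP enrichment.

    The p-value is a one-sided binomial test of chip_sum successes among
    chip_sum + input_sum trials with success probability equal to the ChIP
    share of the combined library size (weighted sums rounded half-up);
    the log2 ratio applies a 0.5 pseudocount to both sums before
    library-size normalization.  Windows with no points are omitted.
    """
    if window_size <= 0:
        raise ParameterError(f"window_size must be positive, got {window_size}")
    if step is None:
        step = window_size // 2
    if step <= 0:
        raise ParameterError(f"step must be positive, got {step}")
    if chip.library_size <= 0 or input_.library_size <= 0:
        raise ParameterError("both libraries must contain points")

    p0 = chip.library_size / (chip.library_size + input_.library_size)
    frames = []
    for contig, L in contig_lengths.items():
        if contig in exclude_contigs:
            continue
        n_win = max(0, (L - window_size) // step + 1)
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * step
        ends = starts + window_size
        cs = chip.window_sums(contig, starts, ends)
        is_ = input_.window_sums(contig, starts, ends)
        keep = (cs + is_) > 0
        if not keep.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": starts[keep],
                    "end": ends[keep],
                    "chip_sum": cs[keep],
                    "input_sum": is_[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    win = pd.concat(frames, ignore_index=True)

    norm_chip = (win["chip_sum"] + 0.5) / chip.library_size
    norm_input = (win["input_sum"] + 0.5) / input_.library_size
    win["log2_ratio"] = np.log2(norm_chip / norm_input)
    k = _round_half_up(win["chip_sum"].to_numpy())
    n = k + _round_half_up(win["input_sum"].to_numpy())
    win["p_value"] = binomial_tail_p(k, n, p0)
    return win


def binomial_tail_p(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """One-sided P(X >= k) for X ~ Binomial(n, p0)."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    return np.clip(stats.binom.sf(k - 1, n, p0), 0.0, 1.0)


def phred(p: np.ndarray, cap: float = PHRED_CAP) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = -10.0 * np.log10(np.asarray(p, dtype=float))
    return np.clip(out, 0.0, cap)


def attach_fdr(windows: pd.DataFrame, swapped_windows: pd.DataFrame) -> pd.DataFrame:
    """Add phred-scaled BH Q-values and label-swap empirical FDRs.

    The empirical FDR at a window with p-value p is
    max(1, #swapped windows with p' <= p) / #real windows with p' <= p,
    phred-scaled and capped at 100.
    """
    win = windows.copy()
    if win.empty:
        win["q_phred"] = pd.Series(dtype=float)
        win["efdr_phred"] = pd.Series(dtype=float)
        return win
    p = win["p_value"].to_numpy()
    q = multipletests(p, method="fdr_bh")[1]
    win["q_phred"] = phred(q)

    swapped_p = np.sort(swapped_windows["p_value"].to_numpy()) if len(swapped_windows) else np.array([])
    real_sorted = np.sort(p)
    n_swapped = np.searchsorted(swapped_p, p, side="right")
    n_real = np.searchsorted(real_sorted, p, side="right")
    efdr = np.maximum(n_swapped, 1) / np.maximum(n_real, 1)
    win["efdr_phred"] = phred(efdr)
    return win


@dataclass
class EnrichedRegion:
    contig: str
    start: int
    end: int
    n_windows: int
    best_p: float
    best_q_phred: float
    best_log2: float


def make_regions(
    windows: pd.DataFrame,
    q_thresh_phred: float = 20.0,
    efdr_thresh_phred: float = 13.0,
    log2_thresh: float = 1.0,
) -> pd.DataFrame:
    """Merge threshold-passing windows into non-overlapping regions.

    Overlapping or adjacent passing windows merge; each region records its
    best (lowest-p) window's statistics.
    """
    passing = windows[
        (windows["q_phred"] >= q_thresh_phred)
        & (windows["efdr_phred"] >= efdr_thresh_phred)
        & (windows["log2_ratio"] >= log2_thresh)
    ]
    cols = ["contig", "start", "end", "n_windows", "best_p", "best_q_phred", "best_log2"]
    if passing.empty:
        return pd.DataFrame(columns=cols)
    regions: list[EnrichedRegion] = []
    for contig, grp in passing.groupby("contig", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur: EnrichedRegion | None = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur.end:  # overlap or adjacency
                cur.end = max(cur.end, row.end)
                cur.n_windows += 1
                if row.p_value < cur.best_p:
                    cur.best_p = row.p_value
                    cur.best_q_phred = row.q_phred
                    cur.best_log2 = row.log2_ratio
            else:
                if cur is not None:
                    regions.append(cur)
                cur = EnrichedRegion(
                    contig, int(row.start), int(row.end), 1, row.p_value, row.q_phred, row.log2_ratio
                )
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(
        [(r.contig, r.start, r.end, r.n_windows, r.best_p, r.best_q_phred, r.best_log2) for r in regions],
        columns=cols,
    )


def intersect_annotation(
    regions: pd.DataFrame, annotation: Sequence[AnnotatedElement]
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag elements overlapped >= 1 bp by any region; tally by class.

    Returns (per-class counts of enriched elements, table of flagged
    elements with the overlapping region index).
    """
    flagged = []
    for i, el in enumerate(annotation):
        sub = regions[regions["contig"] == el.contig]
        hit = sub[(sub["start"] < el.end) & (sub["end"] > el.start)]
        if len(hit):
            flagged.append(
                (el.element_id, el.family, el.element_class, el.contig, el.start, el.end, int(hit.index[0]))
            )
    flagged_df = pd.DataFrame(
        flagged,
        columns=["element_id", "family", "element_class", "contig", "start", "end", "region_index"],
    )
    if flagged_df.empty:
        tallies = pd.Series(dtype=int, name="n_enriched")
    else:
        tallies = flagged_df["element_class"].value_counts().rename("n_enriched")
    return tallies, flagged_df


def score_elements(
    annotation: Sequence[AnnotatedElement],
    chip: PointData,
    input_: PointData,
    q_thresh_phred: float = 70.0,
) -> pd.DataFrame:
    """Score each annotated element over its own span.

    Same statistics as :func:`scan_windows` but on element intervals, with
    BH adjustment across elements; elements at or above the phred Q-value
    threshold (default 70) are flagged high-confidence, and zero-coverage
    elements are flagged rather than omitted.
    """
    if chip.library_size <= 0 or input_.library_size <= 0:
        raise ParameterError("both libraries must contain points")
    p0 = chip.library_size / (chip.library_size + input_.library_size)
    rows = []
    for el in annotation:
        starts = np.array([el.start])
        ends = np.array([el.end])
        cs = float(chip.window_sums(el.contig, starts, ends)[0])
        is_ = float(input_.window_sums(el.contig, starts, ends)[0])
        rows.append((el.element_id, el.family, el.element_class, el.contig, el.start, el.end, cs, is_))
    df = pd.DataFrame(
        rows,
        columns=["element_id", "family", "element_class", "contig", "start", "end", "chip_sum", "input_sum"],
    )
    norm_chip = (df["chip_sum"] + 0.5) / chip.library_size
    norm_input = (df["input_sum"] + 0.5) / input_.library_size
    df["occupancy_score"] = np.log2(norm_chip / norm_input)
    k = _round_half_up(df["chip_sum"].to_numpy())
    n = k + _round_half_up(df["input_sum"].to_numpy())
    df["p_value"] = binomial_tail_p(k, n, p0)
    df["q_phred"] = phred(multipletests(df["p_value"], method="fdr_bh")[1]) if len(df) else []
    df["has_coverage"] = (df["chip_sum"] + df["input_sum"]) > 0
    df["high_confidence"] = (df["q_phred"] >= q_thresh_phred) & df["has_coverage"]
    return df
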