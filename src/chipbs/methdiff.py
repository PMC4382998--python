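"""Methylation enrichment tests of ChIP-captured DNA versus input.

Windows of a fixed number of consecutive CpG sites (default 10, sliding
one CpG at a time, so every window carries comparable information even in
CpG-sparse regions) are tested with a two-sided Fisher exact test on the
(methylated, unmethylated) x (ChIP, input) table; windows where either
library has fewer than the minimum observations (default 10) are skipped.
P-values are BH-adjusted across tested windows and windows are reported
when the phred-scaled FDR reaches the threshold (default 13) and the
absolute log2 methylation ratio reaches its floor (default 0).  The same
Fisher test applied to per-element aggregate counts, followed by per-class
tallies, yields the fraction of each element class (Alu SINEs, tRNA
genes, ...) with significant methylation enrichment in the ChIP.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotatedElement
from .occupancy import phred

_TIE_REL_TOL = 1e-7  # tables whose probability is within this relative
# tolerance of the observed table's count as ties (two-sided rule)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table (ties
    included).  An all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("fisher_exact_2x2 requires non-negative counts")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(support)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    if p >= 1.0 - 1e-12:  # all tables included; absorb float pmf round-off
        return 1.0
    return p


def _window_frame(
    chip_calls: pd.DataFrame, input_calls: pd.DataFrame
) -> pd.DataFrame:
    """Join the two call sets on CpG sites covered in both libraries."""
    keys = ["contig", "pos", "strand"]
    chip = chip_calls[chip_calls["context"] == "CpG"][keys + ["meth", "unmeth"]]
    inp = input_calls[input_calls["context"] == "CpG"][keys + ["meth", "unmeth"]]
    merged = chip.merge(inp, on=keys, suffixes=("_chip", "_input"))
    return merged.sort_values(["contig", "pos"]).reset_index(drop=True)


def test_methylation_windows(
    chip_calls: pd.DataFrame,
    input_calls: pd.DataFrame,
    window_cpgs: int = 10,
    min_obs: int = 10,
    fdr_thresh_phred: float = 13.0,
    log2_thresh: float = 0.0,
) -> pd.DataFrame:
    """Sliding CpG-window Fisher tests of ChIP vs input methylation.

    Returns every tested window with counts, direction, p-value, phred FDR
    and a ``reported`` flag for windows passing both thresholds.
    """
    sites = _window_frame(chip_calls, input_calls)
    cols = [
        "contig",
        "start",
        "end",
        "n_cpgs",
        "chip_meth",
        "chip_unmeth",
        "input_meth",
        "input_unmeth",
        "log2_meth_ratio",
        "direction",
        "p_value",
        "fdr_phred",
        "reported",
    ]
    if sites.empty:
        out = pd.DataFrame(columns=cols)
        out.attrs["empty_reason"] = "no CpG site is covered in both libraries"
        return out

    rows = []
    for contig, grp in sites.groupby("contig", sort=True):
        cm = grp["meth_chip"].to_numpy()
        cu = grp["unmeth_chip"].to_numpy()
        im = grp["meth_input"].to_numpy()
        iu = grp["unmeth_input"].to_numpy()
        pos = grp["pos"].to_numpy()
        n_sites = len(grp)
        if n_sites < window_cpgs:
            continue
        win = np.ones(window_cpgs)
        s_cm = np.convolve(cm, win, mode="valid")
        s_cu = np.convolve(cu, win, mode="valid")
        s_im = np.convolve(im, win, mode="valid")
        s_iu = np.convolve(iu, win, mode="valid")
        for j in range(n_sites - window_cpgs + 1):
            chip_tot = s_cm[j] + s_cu[j]
            inp_tot = s_im[j] + s_iu[j]
            if chip_tot < min_obs or inp_tot < min_obs:
                continue
            rows.append(
                (
                    contig,
                    int(pos[j]),
                    int(pos[j + window_cpgs - 1]) + 1,
                    window_cpgs,
                    s_cm[j],
                    s_cu[j],
                    s_im[j],
                    s_iu[j],
                )
            )
    if not rows:
        out = pd.DataFrame(columns=cols)
        out.attrs["empty_reason"] = (
            f"no window of {window_cpgs} CpGs reaches {min_obs} observations in both libraries"
        )
        return out
    df = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "n_cpgs", "chip_meth", "chip_unmeth", "input_meth", "input_unmeth"],
    )
    chip_frac = (df["chip_meth"] + 0.5) / (df["chip_meth"] + df["chip_unmeth"] + 1.0)
    input_frac = (df["input_meth"] + 0.5) / (df["input_meth"] + df["input_unmeth"] + 1.0)
    df["log2_meth_ratio"] = np.log2(chip_frac / input_frac)
    df["direction"] = np.where(df["log2_meth_ratio"] >= 0, "enriched", "reduced")
    df["p_value"] = [
        fisher_exact_2x2(
            int(round(r.chip_meth)),
            int(round(r.chip_unmeth)),
            int(round(r.input_meth)),
            int(round(r.input_unmeth)),
        )
        for r in df.itertuples()
    ]
    df["fdr_phred"] = phred(multipletests(df["p_value"], method="fdr_bh")[1])
    df["reported"] = (df["fdr_phred"] >= fdr_thresh_phred) & (
        df["log2_meth_ratio"].abs() >= log2_thresh
    )
    return df


def score_region_methylation(
    elements: Sequence[AnnotatedElement], calls: pd.DataFrame
) -> pd.DataFrame:
    """Percent methylation of each element over its covered CpG calls.

    percent_meth = 100 * sum(meth) / sum(meth + unmeth) over CpG calls in
    the element span; elements with no covered CpG are flagged
    (``covered`` False) rather than scored.
    """
    cpg = calls[calls["context"] == "CpG"]
    rows = []
    for el in elements:
        sub = cpg[(cpg["contig"] == el.contig) & (cpg["pos"] >= el.start) & (cpg["pos"] < el.end)]
        meth = float(sub["meth"].sum())
        total = meth + float(sub["unmeth"].sum())
        rows.append(
            (
                el.element_id,
                el.family,
                el.element_class,
                meth,
                total,
                100.0 * meth / total if total > 0 else np.nan,
                total > 0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["element_id", "family", "element_class", "meth_sum", "total_sum", "percent_meth", "covered"],
    )


def test_element_methylation(
    elements: Sequence[AnnotatedElement],
    chip_calls: pd.DataFrame,
    input_calls: pd.DataFrame,
    min_obs: int = 10,
    fdr_thresh_phred: float = 13.0,
) -> pd.DataFrame:
    """Per-element Fisher test of ChIP vs input CpG methylation.

    Aggregates CpG counts over each element span, requires ``min_obs``
    observations per library, BH-adjusts across tested elements and flags
    elements significantly methylation-enriched in the ChIP.
    """
    chip_scores = score_region_methylation(elements, chip_calls)
    input_scores = score_region_methylation(elements, input_calls)
    df = chip_scores.merge(
        input_scores, on=["element_id", "family", "element_class"], suffixes=("_chip", "_input")
    )
    df["tested"] = (df["total_sum_chip"] >= min_obs) & (df["total_sum_input"] >= min_obs)
    p = np.ones(len(df))
    for i, r in enumerate(df.itertuples()):
        if not r.tested:
            continue
        p[i] = fisher_exact_2x2(
            int(round(r.meth_sum_chip)),
            int(round(r.total_sum_chip - r.meth_sum_chip)),
            int(round(r.meth_sum_input)),
            int(round(r.total_sum_input - r.meth_sum_input)),
        )
    df["p_value"] = p
    df["fdr_phred"] = 0.0
    tested = df["tested"].to_numpy()
    if tested.any():
        df.loc[tested, "fdr_phred"] = phred(
            multipletests(df.loc[tested, "p_value"], method="fdr_bh")[1]
        )
    df["direction"] = np.where(
        df["percent_meth_chip"].fillna(0) >= df["percent_meth_input"].fillna(0),
        "enriched",
        "reduced",
    )
    df["significant"] = df["tested"] & (df["fdr_phred"] >= fdr_thresh_phred) & (
        df["direction"] == "enriched"
    )
    return df


def fraction_significant(element_tests: pd.DataFrame) -> pd.DataFrame:
    """Per-class fraction of tested elements with significant enrichment.

    The computational analogue of "X% of Alu SINEs show statistically
    significant enrichment for CpG methylation in the ChIP".
    """
    out = []
    for cls, grp in element_tests.groupby("element_class", sort=True):
        n_tested = int(grp["tested"].sum())
        n_sig = int(grp["significant"].sum())
        out.append(
            (cls, n_tested, n_sig, 100.0 * n_sig / n_tested if n_tested else np.nan)
        )
    return pd.DataFrame(
        out, columns=["element_class", "n_tested", "n_significant", "percent_significant"]
    )
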