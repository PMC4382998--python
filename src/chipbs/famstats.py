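"""Family-level comparisons of occupancy and methylation.

Occupancy scores and percent-methylation values are compared across repeat
families with the tie-corrected Kruskal-Wallis test followed by Dunn's
pairwise z tests (Bonferroni-adjusted by default), and the joint
occupancy-methylation relationship is summarized as a moving average over
blocks of elements ordered by methylation (default 25 elements per block).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value."""

    H: float
    df: int
    p_value: float
    group_sizes: list[int]
    mean_ranks: list[float]


@dataclass
class DunnResult:
    """Pairwise Dunn z tests after a Kruskal-Wallis comparison."""

    table: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    adjustment: str


def _ranks_and_ties(groups: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Mid-ranks of the pooled data split back per group, and sum(t^3 - t)."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    out = []
    i = 0
    for g in groups:
        out.append(ranks[i : i + len(g)])
        i += len(g)
    return out, tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis rank test with mid-rank tie correction.

    H = [12 / (n(n+1)) * sum n_i (Rbar_i - (n+1)/2)^2] / C with the tie
    correction C = 1 - sum(t^3 - t) / (n^3 - n); p from chi-square with
    g - 1 degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("kruskal_wallis requires at least 2 groups")
    if any(len(g) == 0 for g in arrays):
        raise ParameterError("kruskal_wallis groups must be non-empty")
    n = sum(len(g) for g in arrays)
    if n < 3:
        raise ParameterError("kruskal_wallis requires at least 3 observations")
    group_ranks, tie_term = _ranks_and_ties(arrays)
    mean_ranks = [float(r.mean()) for r in group_ranks]
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (rb - (n + 1) / 2.0) ** 2 for g, rb in zip(arrays, mean_ranks)
    )
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:  # all values identical
        h_corr = 0.0
        p = 1.0
    else:
        h_corr = h / correction
        p = float(stats.chi2.sf(h_corr, df=len(arrays) - 1))
    return KWResult(
        H=float(h_corr),
        df=len(arrays) - 1,
        p_value=p,
        group_sizes=[len(g) for g in arrays],
        mean_ranks=mean_ranks,
    )


def dunn_test(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> DunnResult:
    """Dunn's multiple-comparison z tests on the pooled mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(n(n+1)/12 - tie/(12(n-1))) (1/n_i + 1/n_j)]
    with two-sided normal p-values, adjusted over all g(g-1)/2 pairs by
    Bonferroni (default), Holm, or left raw ("none").
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("dunn_test requires at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    n = sum(len(g) for g in arrays)
    group_ranks, tie_term = _ranks_and_ties(arrays)
    mean_ranks = [float(r.mean()) for r in group_ranks]
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        denom = np.sqrt(var_base * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z))) if denom > 0 else 1.0
        rows.append((labels[i], labels[j], float(z), p_raw))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    m = len(df)
    if adjustment == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    elif adjustment == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif adjustment == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise ParameterError(f"unknown adjustment {adjustment!r}")
    return DunnResult(table=df, adjustment=adjustment)


def moving_average_curve(
    elements: pd.DataFrame,
    block: int = 25,
    *,
    meth_col: str = "percent_meth",
    occ_col: str = "occupancy_score",
) -> pd.DataFrame:
    """Occupancy-vs-methylation moving average over methylation-sorted blocks.

    Elements with a missing value on either axis are excluded; the
    remainder are sorted by methylation and averaged over contiguous
    blocks sliding by one element, giving n - block + 1 curve points.
    """
    if block < 1:
        raise ParameterError("block must be >= 1")
    df = elements[[meth_col, occ_col]].dropna().sort_values(meth_col, kind="stable")
    n = len(df)
    if n < block:
        raise ParameterError(f"need at least block={block} scored elements, have {n}")
    kernel = np.ones(block) / block
    meth = np.convolve(df[meth_col].to_numpy(), kernel, mode="valid")
    occ = np.convolve(df[occ_col].to_numpy(), kernel, mode="valid")
    return pd.DataFrame({"mean_meth": meth, "mean_occupancy": occ})


@dataclass
class FamilyComparison:
    """Joined per-family summary with KW/Dunn results on both axes."""

    summary: pd.DataFrame
    elements: pd.DataFrame
    kw_occupancy: KWResult | None
    kw_methylation: KWResult | None
    dunn_occupancy: DunnResult | None
    dunn_methylation: DunnResult | None
    skipped_reason: str | None = None


def family_summary(
    element_scores: pd.DataFrame,
    meth_scores: pd.DataFrame,
    *,
    min_group_size: int = 2,
    enriched_only: bool = False,
    adjustment: str = "bonferroni",
) -> FamilyComparison:
    """Per-family occupancy/methylation summary with KW + Dunn tests.

    Joins the element occupancy table (``element_id``, ``family``,
    ``occupancy_score``, optionally ``high_confidence``) with the percent
    methylation table on element id.  With ``enriched_only`` the
    comparison is restricted to high-confidence occupied elements.  A
    single usable family skips the tests with a reason instead of failing.
    """
    joined = element_scores.merge(
        meth_scores[["element_id", "percent_meth", "covered"]], on="element_id"
    )
    joined = joined[joined["covered"]]
    if enriched_only and "high_confidence" in joined:
        joined = joined[joined["high_confidence"]]
    summary = (
        joined.groupby("family")
        .agg(
            n=("element_id", "size"),
            median_occupancy=("occupancy_score", "median"),
            mean_occupancy=("occupancy_score", "mean"),
            median_percent_meth=("percent_meth", "median"),
            mean_percent_meth=("percent_meth", "mean"),
        )
        .reset_index()
        .sort_values("family")
        .reset_index(drop=True)
    )
    usable = summary[summary["n"] >= min_group_size]["family"].tolist()
    if len(usable) < 2:
        return FamilyComparison(
            summary=summary,
            elements=joined,
            kw_occupancy=None,
            kw_methylation=None,
            dunn_occupancy=None,
            dunn_methylation=None,
            skipped_reason=f"only {len(usable)} family with enough elements; tests need >= 2",
        )
    occ_groups = [
        joined.loc[joined["family"] == f, "occupancy_score"].to_numpy() for f in usable
    ]
    meth_groups = [
        joined.loc[joined["family"] == f, "percent_meth"].to_numpy() for f in usable
    ]
    return FamilyComparison(
        summary=summary,
        elements=joined,
        kw_occupancy=kruskal_wallis(occ_groups),
        kw_methylation=kruskal_wallis(meth_groups),
        dunn_occupancy=dunn_test(occ_groups, usable, adjustment),
        dunn_methylation=dunn_test(meth_groups, usable, adjustment),
    )
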