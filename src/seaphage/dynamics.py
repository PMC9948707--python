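"""Temporal-dynamics classification of host ASVs and virus year specificity.

Monthly time series are too coarse to estimate true growth rates (r) or
carrying capacities (K), so two proxies are used: the *r-like index* is the
maximum month-to-month increase of an ASV's normalized community rank
(0..1), and the *K-like index* is the length of its longest run of
consecutive months above 0.1% relative abundance. Persistently dominant
populations have K-like > 12 and r-like < 0.1; temporarily abundant
(opportunistic) populations have K-like < 3 and r-like > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .virome import normalized_rank_matrix

__all__ = [
    "DynamicsClass",
    "r_like_index",
    "k_like_index",
    "classify",
    "classify_community",
    "year_specificity",
    "year_specificity_table",
]


@dataclass(frozen=True)
class DynamicsClass:
    asv_id: str
    r_like: float
    k_like: int
    label: str


def r_like_index(rank_series) -> float:
    """Maximum monthly increase of the normalized relative rank, floored at 0."""
    x = np.asarray(rank_series, dtype=float)
    if x.size < 2:
        raise ValueError("rank series must have at least 2 months")
    if (x < 0).any() or (x > 1).any():
        raise ValueError("normalized ranks must lie in [0, 1]")
    return float(max(np.max(np.diff(x)), 0.0))


def k_like_index(rel_series, threshold: float = 0.001) -> int:
    """Longest run of consecutive months strictly above ``threshold``."""
    x = np.asarray(rel_series, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    best = run = 0
    for v in x:
        run = run + 1 if v > threshold else 0
        best = max(best, run)
    return best


def classify(k_like: int, r_like: float) -> str:
    """persistent (K>12 & r<0.1), temporary (K<3 & r>0.5), else intermediate."""
    if k_like > 12 and r_like < 0.1:
        return "persistent"
    if k_like < 3 and r_like > 0.5:
        return "temporary"
    return "intermediate"


def classify_community(rel: pd.DataFrame, threshold: float = 0.001) -> pd.DataFrame:
    """Indices and labels for every ASV of a relative abundance matrix.

    Normalized ranks are computed among all ASVs present each month (the
    matrix's full row set).
    """
    ranks = normalized_rank_matrix(rel)
    rows = []
    for asv in rel.index:
        r = r_like_index(ranks.loc[asv].to_numpy())
        k = k_like_index(rel.loc[asv].to_numpy(), threshold)
        rows.append(DynamicsClass(asv, r, k, classify(k, r)))
    return pd.DataFrame(
        [(d.asv_id, d.r_like, d.k_like, d.label) for d in rows],
        columns=["asv_id", "r_like", "k_like", "label"],
    ).set_index("asv_id")


def year_specificity(total_a: float, total_b: float, factor: float = 5.0) -> str:
    """'year_a' / 'year_b' if one year's total exceeds ``factor`` times the
    other's (strict), else 'both'."""
    if total_a < 0 or total_b < 0:
        raise ValueError("year totals must be nonnegative")
    if total_a == 0 and total_b == 0:
        raise ValueError("both year totals are zero")
    if total_a > factor * total_b:
        return "year_a"
    if total_b > factor * total_a:
        return "year_b"
    return "both"


def year_specificity_table(
    viral: pd.DataFrame, years, factor: float = 5.0
) -> pd.DataFrame:
    """Year type per contig from per-sample calendar years.

    Year totals are sums of (relative) abundance over each calendar year's
    sampled months; exactly two distinct years are required.
    """
    years = np.asarray(years)
    uniq = sorted(set(years.tolist()))
    if len(uniq) != 2:
        raise ValueError("year_specificity_table expects exactly two calendar years")
    a_cols = viral.columns[years == uniq[0]]
    b_cols = viral.columns[years == uniq[1]]
    rows = []
    for contig in viral.index:
        ta = float(viral.loc[contig, a_cols].sum())
        tb = float(viral.loc[contig, b_cols].sum())
        label = year_specificity(ta, tb, factor)
        label = {"year_a": str(uniq[0]), "year_b": str(uniq[1])}.get(label, "both")
        rows.append((contig, ta, tb, label))
    return pd.DataFrame(
        rows, columns=["contig_id", f"total_{uniq[0]}", f"total_{uniq[1]}", "year_type"]
    ).set_index("contig_id")
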