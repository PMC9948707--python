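"""Viral intrapopulation diversity from per-site allele counts.

Per-site Shannon entropy of the A/C/G/T allele frequencies is averaged over
a contig's sites in one month; the average is only reported when the
contig-month's mean coverage strictly exceeds a gate (default 10x). The
association between average genome entropy and viral abundance across
contig-months is the frequency-dependent-infection signal: more abundant
viral populations accumulate more intrapopulation variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "site_entropy",
    "genome_avg_entropy",
    "entropy_table",
    "entropy_abundance_association",
]


def site_entropy(counts, base: float = np.e) -> float:
    """Shannon entropy of one site's allele counts (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("allele counts must be nonnegative")
    depth = c.sum()
    if depth == 0:
        raise ValueError("site entropy undefined at zero depth")
    p = c[c > 0] / depth
    return float(-(p * (np.log(p) / np.log(base))).sum())


def genome_avg_entropy(
    site_counts: np.ndarray, min_coverage: float = 10.0, base: float = np.e
) -> float | None:
    """Mean site entropy of one contig-month, gated on mean coverage.

    ``site_counts`` is an (n_sites, 4) array of A/C/G/T counts. Returns None
    when there are no sites or the mean depth is not strictly above
    ``min_coverage``; sites with zero depth are excluded from the average.
    """
    counts = np.atleast_2d(np.asarray(site_counts, dtype=float))
    if counts.size == 0:
        return None
    depths = counts.sum(axis=1)
    if depths.mean() <= min_coverage:
        return None
    covered = depths > 0
    if not covered.any():
        return None
    return float(np.mean([site_entropy(row, base=base) for row in counts[covered]]))


def entropy_table(
    allele_counts: pd.DataFrame, min_coverage: float = 10.0, base: float = np.e
) -> pd.DataFrame:
    """Average genome entropy per (contig, month) from a long-format table.

    Expects columns contig, month, position, A, C, G, T (the layout the
    synthetic generator writes). Contig-months failing the coverage gate are
    omitted.
    """
    rows = []
    for (contig, month), grp in allele_counts.groupby(["contig", "month"], sort=False):
        h = genome_avg_entropy(grp[["A", "C", "G", "T"]].to_numpy(), min_coverage, base)
        if h is not None:
            depth = float(grp[["A", "C", "G", "T"]].to_numpy().sum(axis=1).mean())
            rows.append((contig, month, h, depth))
    return pd.DataFrame(rows, columns=["contig", "month", "avg_entropy", "mean_depth"])


def entropy_abundance_association(
    entropies, abundances
) -> tuple[float, float]:
    """Spearman rho and p between average entropy and abundance.

    Inputs are paired across contig-months (at least 6 pairs). A constant
    entropy vector has no defined rank correlation and returns (nan, nan).
    """
    h = np.asarray(entropies, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if h.size != a.size or h.size < 6:
        raise ValueError("need at least 6 paired contig-month observations")
    if np.ptp(h) == 0 or np.ptp(a) == 0:
        return float("nan"), float("nan")
    rho, p = spearmanr(h, a)
    return float(rho), float(p)
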