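"""Host-prediction-constrained virus-host cooccurrence network inference.

The screen computes Spearman correlations between every prokaryotic ASV and
every (abundance-filtered) viral contig over their shared months, adjusts the
p-values by Benjamini-Hochberg within the whole virus-ASV family, and gates
significance at rho > 0.6, P < 0.01, q < 0.05 (one-sided positive: viral
production tracks host density). A significant pair only counts as a
cooccurring virus-host pair when the contig's predicted host group matches
the ASV's taxon ("supported"). Significant-but-unsupported pairs that are
explainable through a supported partner (the virus cooccurs with a supported
ASV that itself cooccurs with the unsupported ASV) are pruned as transitive
false positives.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr, t as t_dist
from statsmodels.stats.multitest import multipletests

from .virome import normalized_rank_matrix

__all__ = [
    "spearman_matrix",
    "screen",
    "asv_asv_pairs",
    "prune_transitive",
    "to_absolute",
    "env_correlations",
    "summarize_network",
    "rank_vs_density",
]

RHO_MIN = 0.6
P_MAX = 0.01
Q_MAX = 0.05


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p between rows of a and rows of b.

    Vectorised rank correlation with the t-distribution p-value approximation
    (the same approximation scipy.stats.spearmanr uses for small samples).
    """
    n = a.shape[1]
    if n != b.shape[1] or n < 3:
        raise ValueError("matrices must share at least 3 sample columns")
    ra = np.apply_along_axis(rankdata, 1, a.to_numpy(dtype=float))
    rb = np.apply_along_axis(rankdata, 1, b.to_numpy(dtype=float))
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=1))
    nb = np.sqrt((rb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra @ rb.T) / np.outer(na, nb)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(np.abs(tval), df=n - 2)
    p = np.where(np.isnan(tval), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    return rho, p


def screen(
    asv_rel: pd.DataFrame,
    viral: pd.DataFrame,
    host_group: dict[str, str | None],
    taxon_of_asv: dict[str, str],
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
    q_max: float = Q_MAX,
    mode: str = "relative",
) -> pd.DataFrame:
    """Spearman screen of all (ASV, contig) pairs over shared months.

    Returns one row per tested pair with rho, p, BH-adjusted q, the
    significance gate (rho > rho_min AND p < p_max AND q < q_max), the host
    support flag, and ``cooccurring = significant & supported``.
    """
    shared = [c for c in asv_rel.columns if c in set(viral.columns)]
    if len(shared) < 6:
        raise ValueError("fewer than 6 shared samples; correlation screen refused")
    a = asv_rel[shared]
    v = viral[shared]
    rho, p = spearman_matrix(a, v)
    rows = []
    for i, asv in enumerate(a.index):
        for j, contig in enumerate(v.index):
            rows.append((asv, contig, rho[i, j], p[i, j]))
    df = pd.DataFrame(rows, columns=["asv_id", "contig_id", "rho", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["rho"] > rho_min) & (df["p"] < p_max) & (df["q"] < q_max)
    df["supported"] = [
        host_group.get(c) is not None and host_group.get(c) == taxon_of_asv.get(a)
        for a, c in zip(df["asv_id"], df["contig_id"])
    ]
    df["cooccurring"] = df["significant"] & df["supported"]
    df["pruned"] = False
    df["mode"] = mode
    return df


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def asv_asv_pairs(
    asv_rel: pd.DataFrame,
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
    q_max: float = Q_MAX,
) -> pd.DataFrame:
    """Significant ASV-ASV cooccurrences (their own BH family, same gate)."""
    rho, p = spearman_matrix(asv_rel, asv_rel)
    ids = list(asv_rel.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], rho[i, j], p[i, j]))
    df = pd.DataFrame(rows, columns=["asv_a", "asv_b", "rho", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["rho"] > rho_min) & (df["p"] < p_max) & (df["q"] < q_max)
    return df


def prune_transitive(pairs: pd.DataFrame, asv_pairs: pd.DataFrame) -> pd.DataFrame:
    """Mark unsupported significant pairs explainable via a supported partner.

    An unsupported pair (virus A, ASV X) is pruned iff some ASV Y exists with
    (A, Y) significant and supported and (X, Y) a significant ASV-ASV pair.
    Supported pairs are never pruned.
    """
    out = pairs.copy()
    sig_asv = asv_pairs[asv_pairs["significant"]]
    neighbours: dict[str, set[str]] = {}
    for a, b in zip(sig_asv["asv_a"], sig_asv["asv_b"]):
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    supported_by_virus: dict[str, set[str]] = {}
    sup = out[out["significant"] & out["supported"]]
    for v, a in zip(sup["contig_id"], sup["asv_id"]):
        supported_by_virus.setdefault(v, set()).add(a)
    pruned = []
    for _, row in out.iterrows():
        flag = False
        if row["significant"] and not row["supported"]:
            partners = supported_by_virus.get(row["contig_id"], set())
            flag = bool(partners & neighbours.get(row["asv_id"], set()))
        pruned.append(flag)
    out["pruned"] = pruned
    return out


def to_absolute(rel: pd.DataFrame, counts: pd.Series) -> pd.DataFrame:
    """Absolute abundance = relative abundance x per-sample cell/VLP count.

    Samples without a count are dropped; negative counts are rejected.
    """
    counts = counts.reindex(rel.columns)
    keep = counts.notna()
    if (counts[keep] < 0).any():
        raise ValueError("cell/VLP counts must be nonnegative")
    return rel.loc[:, keep.to_numpy()].mul(counts[keep], axis=1)


def env_correlations(
    asv_rel: pd.DataFrame,
    variables: pd.DataFrame,
    rho_min: float = RHO_MIN,
    p_max: float = P_MAX,
    q_max: float = Q_MAX,
) -> pd.DataFrame:
    """Signed significant Spearman correlations with environmental variables.

    ``variables`` has samples as rows and one column per variable; the gate
    is two-sided (|rho| > rho_min, p < p_max, q < q_max) and q forms its own
    BH family. Constant variables are skipped with a warning.
    """
    shared = [c for c in asv_rel.columns if c in set(variables.index)]
    rows = []
    for var in variables.columns:
        series = variables.loc[shared, var].to_numpy(dtype=float)
        if np.ptp(series) == 0:
            warnings.warn(f"environmental variable {var!r} is constant; skipped")
            continue
        for asv in asv_rel.index:
            rho, p = spearmanr(asv_rel.loc[asv, shared].to_numpy(), series)
            rows.append((asv, var, rho, p))
    df = pd.DataFrame(rows, columns=["asv_id", "variable", "rho", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["rho"].abs() > rho_min) & (df["p"] < p_max) & (df["q"] < q_max)
    df["sign"] = np.sign(df["rho"]).astype(int)
    return df


def summarize_network(
    pairs: pd.DataFrame, all_asvs: list[str], taxon_of_asv: dict[str, str] | None = None
) -> dict:
    """Degrees, median cooccurring viruses per ASV, and per-taxon totals."""
    cooc = pairs[pairs["cooccurring"]]
    degree = {a: 0 for a in all_asvs}
    for a in cooc["asv_id"]:
        degree[a] = degree.get(a, 0) + 1
    deg = pd.Series(degree, dtype=int)
    summary = {
        "degree": deg,
        "median_viruses_per_asv": float(deg.median()),
        "n_pairs": int(len(cooc)),
    }
    if taxon_of_asv is not None:
        by_taxon = cooc.groupby(cooc["asv_id"].map(taxon_of_asv)).size()
        summary["pairs_by_taxon"] = by_taxon.to_dict()
    return summary


def rank_vs_density(
    viral: pd.DataFrame,
    host_rel: pd.DataFrame,
    pairs: pd.DataFrame,
    bin_edges: tuple[float, float] = (0.001, 0.01),
) -> pd.DataFrame:
    """Normalized viral community rank pooled by host-density bin.

    For every (cooccurring) pair and month, the virus's normalized rank in
    the viral community is assigned to a bin by its host's relative abundance
    (default edges 0.1% and 1%). Returns per-bin quartiles and counts.
    """
    lo, hi = bin_edges
    ranks = normalized_rank_matrix(viral)
    pooled: dict[str, list[float]] = {"<0.1%": [], "0.1-1%": [], ">1%": []}
    use = pairs[pairs["cooccurring"]] if "cooccurring" in pairs else pairs
    shared = [c for c in viral.columns if c in set(host_rel.columns)]
    for _, row in use.iterrows():
        contig, asv = row["contig_id"], row["asv_id"]
        if contig not in ranks.index or asv not in host_rel.index:
            continue
        for month in shared:
            h = host_rel.loc[asv, month]
            bin_name = ">1%" if h >= hi else ("0.1-1%" if h >= lo else "<0.1%")
            pooled[bin_name].append(float(ranks.loc[contig, month]))
    rows = []
    for name, values in pooled.items():
        v = np.array(values)
        rows.append(
            {
                "bin": name,
                "n": v.size,
                "q25": float(np.percentile(v, 25)) if v.size else np.nan,
                "median": float(np.median(v)) if v.size else np.nan,
                "q75": float(np.percentile(v, 75)) if v.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")
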