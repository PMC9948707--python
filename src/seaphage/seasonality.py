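"""Community seasonality: Bray-Curtis similarity versus sampling interval,
season labelling, and (partial) Mantel permutation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .amplicon import bray_curtis_similarity

__all__ = [
    "season_of",
    "similarity_vs_lag",
    "mantel",
    "partial_mantel",
    "bray_curtis_distance_matrix",
    "environment_distance_matrix",
]

_SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of(calendar_month: int) -> str:
    """Season label for a calendar month (3-5 spring, 6-8 summer, 9-11
    autumn, 12/1/2 winter)."""
    if calendar_month not in _SEASONS:
        raise ValueError("calendar month must be in 1..12")
    return _SEASONS[calendar_month]


def similarity_vs_lag(rel: pd.DataFrame, month_index) -> pd.DataFrame:
    """Mean and dispersion of pairwise Bray-Curtis similarity per month lag.

    Every unordered sample pair contributes one similarity at lag
    ``|delta month_index|``. Returns a frame indexed by lag with columns
    mean, sd, n. With 18 consecutive months, lags run 1..17 with 17 down to
    1 pairs.
    """
    if rel.shape[1] < 3:
        raise ValueError("at least 3 samples required")
    idx = np.asarray(month_index, dtype=int)
    if idx.size != rel.shape[1]:
        raise ValueError("month_index length must match the number of samples")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicate month_index values")
    cols = rel.to_numpy().T
    per_lag: dict[int, list[float]] = {}
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            lag = abs(int(idx[i]) - int(idx[j]))
            per_lag.setdefault(lag, []).append(bray_curtis_similarity(cols[i], cols[j]))
    out = pd.DataFrame(
        {
            "lag": sorted(per_lag),
            "mean": [float(np.mean(per_lag[k])) for k in sorted(per_lag)],
            "sd": [float(np.std(per_lag[k], ddof=1)) if len(per_lag[k]) > 1 else np.nan
                   for k in sorted(per_lag)],
            "n": [len(per_lag[k]) for k in sorted(per_lag)],
        }
    ).set_index("lag")
    return out


def bray_curtis_distance_matrix(rel: pd.DataFrame) -> np.ndarray:
    """Square Bray-Curtis dissimilarity matrix between sample columns."""
    return squareform(pdist(rel.to_numpy().T, metric="braycurtis"))


def environment_distance_matrix(variables: pd.DataFrame) -> np.ndarray:
    """Euclidean distance between samples on z-scored variables.

    ``variables`` has samples as rows. Combined environmental / nutrient
    matrices are built by passing the respective variable subsets.
    """
    x = variables.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant variable has no z-score")
    return squareform(pdist((x - mu) / sd, metric="euclidean"))


def _validate_square(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _tri(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], 1)
    return d[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    return float(x @ y / denom) if denom > 0 else np.nan


def mantel(
    dx: np.ndarray,
    dy: np.ndarray,
    n_perm: int = 9_999,
    seed: int | np.random.Generator = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """One-sided (greater) Mantel permutation test between distance matrices.

    rho is the rank (or product-moment) correlation of the upper triangles;
    the permutation null jointly relabels the rows and columns of ``dy``, and
    p uses the add-one estimator (1 + #{rho_perm >= rho}) / (1 + n_perm).
    """
    dx = _validate_square(dx, "dx")
    dy = _validate_square(dy, "dy")
    if dx.shape != dy.shape:
        raise ValueError("distance matrices must have the same shape")
    n = dx.shape[0]
    if n < 4:
        raise ValueError("mantel needs at least 4 objects")
    x = _tri(dx)
    rho = _corr(x, _tri(dy), method)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho_p = _corr(x, _tri(dy[np.ix_(perm, perm)]), method)
        if rho_p >= rho:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)


def partial_mantel(
    dx: np.ndarray,
    dy: np.ndarray,
    dz: np.ndarray,
    n_perm: int = 9_999,
    seed: int | np.random.Generator = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Mantel test between dx and dy controlling for dz.

    The upper triangles of dx and dy (rank-transformed for the Spearman
    variant) are each residualised on dz by least squares; rho is the
    correlation of the residuals. The permutation relabels dx with dz held
    fixed; p is one-sided (greater) with the add-one estimator.
    """
    dx = _validate_square(dx, "dx")
    dy = _validate_square(dy, "dy")
    dz = _validate_square(dz, "dz")
    if not dx.shape == dy.shape == dz.shape:
        raise ValueError("distance matrices must have the same shape")
    n = dx.shape[0]
    if n < 4:
        raise ValueError("partial_mantel needs at least 4 objects")

    def prep(v: np.ndarray) -> np.ndarray:
        return rankdata(v) if method == "spearman" else np.asarray(v, dtype=float)

    z = prep(_tri(dz))
    zc = np.column_stack([np.ones_like(z), z])

    def resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(zc, v, rcond=None)
        return v - zc @ beta

    ry = resid(prep(_tri(dy)))
    rx = resid(prep(_tri(dx)))

    def pcorr(u: np.ndarray, v: np.ndarray) -> float:
        # a matrix fully explained by the control leaves nothing to correlate
        if np.linalg.norm(u) < 1e-10 or np.linalg.norm(v) < 1e-10:
            return 0.0
        return _corr(u, v, "pearson")

    rho = pcorr(rx, ry)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rxp = resid(prep(_tri(dx[np.ix_(perm, perm)])))
        if pcorr(rxp, ry) >= rho:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)
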