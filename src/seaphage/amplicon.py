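"""Prokaryotic amplicon processing: rarefaction, abundant-OTU selection,
minimum-entropy decomposition (MED) into ASVs, and diversity indices.

MED recursively partitions an alignment of equal-length reads at its
highest-entropy position (Shannon entropy in bits over the residue
distribution, weighted by read counts) until every position falls below an
entropy threshold; the resulting leaves are candidate amplicon sequence
variants (ASVs). Candidates are kept only if the copy number of their most
abundant sequence exceeds ``min_top_count`` and their share of the parent
OTU's reads exceeds ``min_fraction`` (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import entropy as _shannon

__all__ = [
    "AsvRecord",
    "DiversityProfile",
    "rarefy",
    "to_relative",
    "abundant_entities",
    "med_decompose",
    "diversity",
    "bray_curtis_similarity",
]


@dataclass(frozen=True)
class AsvRecord:
    asv_id: str
    parent_otu: str
    template_sequence: str
    count: int
    taxon: str | None = None


@dataclass(frozen=True)
class DiversityProfile:
    shannon: float
    richness: int
    evenness: float


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise a count matrix to relative abundances."""
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("cannot normalise all-zero sample columns")
    return counts / sums


def rarefy(
    counts: pd.DataFrame, depth: int | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Subsample each sample column to a common depth without replacement.

    ``depth=None`` uses the minimum column sum. Samples with fewer reads than
    ``depth`` are dropped with a warning. A single seeded draw is made per
    sample (multivariate hypergeometric), not an average over draws.
    """
    sums = counts.sum(axis=0).astype(np.int64)
    if depth is None:
        depth = int(sums.min())
    if depth < 0:
        raise ValueError("rarefaction depth must be nonnegative")
    keep = [c for c in counts.columns if sums[c] >= depth]
    dropped = [c for c in counts.columns if sums[c] < depth]
    if dropped:
        warnings.warn(f"samples below rarefaction depth excluded: {dropped}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for c in keep:
        col = counts[c].to_numpy(dtype=np.int64)
        out[c] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index)


def abundant_entities(rel: pd.DataFrame, cutoff: float = 0.01) -> list[str]:
    """Entities reaching ``cutoff`` relative abundance in at least one sample.

    The boundary is inclusive (>= cutoff), so an OTU peaking at exactly 1%
    counts as abundant.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    mask = (rel >= cutoff).any(axis=1)
    return list(rel.index[mask])


def _positional_entropies(seqs: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Count-weighted base-2 Shannon entropy at each alignment column."""
    n_pos = seqs.shape[1]
    ents = np.empty(n_pos)
    for j in range(n_pos):
        col = seqs[:, j]
        tot: dict[bytes, float] = {}
        for residue, c in zip(col, counts):
            tot[residue] = tot.get(residue, 0) + c
        p = np.array(list(tot.values()), dtype=float)
        p = p / p.sum()
        ents[j] = _shannon(p, base=2)
    return ents


def med_decompose(
    sequences: list[tuple[str, int]],
    entropy_threshold: float = 0.25,
    min_top_count: int = 50,
    min_fraction: float = 0.01,
    parent_otu: str = "OTU",
) -> list[AsvRecord]:
    """Minimum-entropy decomposition of aligned reads into ASVs.

    ``sequences`` is a list of (sequence, copy number) pairs over one parent
    OTU; all sequences must have equal length. The alignment is split at the
    maximum-entropy position exceeding ``entropy_threshold`` (leftmost on
    ties), partitioning reads by the residue at that position, recursively
    until all positions fall below the threshold. Leaves whose most abundant
    sequence has more than ``min_top_count`` copies AND whose read share of
    the parent exceeds ``min_fraction`` become ASVs, named by decreasing
    abundance.
    """
    if not sequences:
        return []
    lengths = {len(s) for s, _ in sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have the same length")
    if any(c <= 0 for _, c in sequences):
        raise ValueError("sequence counts must be positive")

    seqs = np.array([list(s) for s, _ in sequences], dtype="S1")
    counts = np.array([c for _, c in sequences], dtype=np.int64)
    parent_total = counts.sum()
    leaves: list[np.ndarray] = []

    def split(mask: np.ndarray):
        ents = _positional_entropies(seqs[mask], counts[mask])
        over = ents > entropy_threshold
        if not over.any():
            leaves.append(mask)
            return
        j = int(np.argmax(ents))  # leftmost maximum
        for residue in sorted(set(seqs[mask, j])):
            split(mask & (seqs[:, j] == residue))

    split(np.ones(len(counts), dtype=bool))

    candidates = []
    for mask in leaves:
        leaf_counts = counts[mask]
        if leaf_counts.size == 0:
            continue
        top = int(leaf_counts.max())
        total = int(leaf_counts.sum())
        if top > min_top_count and total / parent_total > min_fraction:
            top_idx = np.flatnonzero(mask)[int(np.argmax(leaf_counts))]
            template = seqs[top_idx].tobytes().decode()
            candidates.append((total, template))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [
        AsvRecord(f"{parent_otu}-{k + 1}", parent_otu, template, total)
        for k, (total, template) in enumerate(candidates)
    ]


def diversity(abundances, base: float = np.e) -> DiversityProfile:
    """Shannon H', richness and Pielou evenness of one sample column.

    H' = -sum p_i log(p_i) over nonzero proportions (log base configurable),
    richness is the number of nonzero entities, and J = H'/log(richness) in
    the same base (defined as 0 for a single entity).
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0:
        raise ValueError("all-zero sample has no diversity profile")
    p = x[x > 0] / x.sum()
    h = float(_shannon(p, base=base))
    richness = int((x > 0).sum())
    j = 0.0 if richness == 1 else h / (np.log(richness) / np.log(base))
    return DiversityProfile(shannon=h, richness=richness, evenness=float(j))


def bray_curtis_similarity(x, y) -> float:
    """1 - Bray-Curtis dissimilarity between two nonnegative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - braycurtis(x, y))
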