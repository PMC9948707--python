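"""Viral-side quantification: dereplication, FPKM, gOTU tables, abundance
filtering and normalized community ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ViralContig",
    "dereplicate",
    "fpkm",
    "abundance_filter",
    "normalized_rank",
    "normalized_rank_matrix",
]


@dataclass(frozen=True)
class ViralContig:
    contig_id: str
    length: int
    circular: bool = False
    gotu: str | None = None
    completeness: float | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("contig length must be positive")


def dereplicate(
    contigs: list[ViralContig],
    pairwise_identity: dict[tuple[str, str], float],
    ani_threshold: float = 95.0,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first clustering at global average nucleotide identity.

    Contigs are visited by decreasing length (id as tiebreak); each joins the
    first existing representative with ANI >= ``ani_threshold``, otherwise it
    founds a new cluster. Returns (representatives, member -> representative).
    """
    ids = {c.contig_id for c in contigs}
    for (a, b), v in pairwise_identity.items():
        if not 0.0 <= v <= 100.0:
            raise ValueError("ANI values must lie in [0, 100]")
        if a not in ids or b not in ids:
            raise ValueError(f"identity entry references unknown contig: {(a, b)}")

    def ani(a: str, b: str) -> float:
        return pairwise_identity.get((a, b), pairwise_identity.get((b, a), 0.0))

    reps: list[str] = []
    membership: dict[str, str] = {}
    for c in sorted(contigs, key=lambda c: (-c.length, c.contig_id)):
        for r in reps:
            if ani(c.contig_id, r) >= ani_threshold:
                membership[c.contig_id] = r
                break
        else:
            reps.append(c.contig_id)
            membership[c.contig_id] = c.contig_id
    return reps, membership


def fpkm(read_counts: pd.DataFrame, lengths: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of contig per million mapped reads.

    FPKM[i, s] = count[i, s] / (length_i / 1e3) / (mapped reads in s / 1e6),
    where the per-sample library size is the mapped-read total of the matrix
    itself. All-zero samples yield zero columns with a warning.
    """
    lengths = pd.Series(lengths).reindex(read_counts.index)
    if lengths.isna().any():
        missing = list(read_counts.index[lengths.isna()])
        raise ValueError(f"missing contig lengths: {missing}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    libsize = read_counts.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        warnings.warn(f"samples with zero mapped reads: {list(read_counts.columns[zero])}")
    denom = libsize.replace(0, np.nan) / 1e6
    per_kb = read_counts.div(lengths / 1e3, axis=0)
    return per_kb.div(denom, axis=1).fillna(0.0)


def abundance_filter(fpkm_matrix: pd.DataFrame, min_fpkm: float = 10.0) -> list[str]:
    """Contigs whose FPKM strictly exceeds ``min_fpkm`` in at least one sample."""
    mask = (fpkm_matrix > min_fpkm).any(axis=1)
    return list(fpkm_matrix.index[mask])


def normalized_rank(abundances) -> np.ndarray:
    """Ascending average ranks mapped to [0, 1]; the most abundant gets 1.

    A single entity maps to 1.0; ties receive the average of their ranks.
    """
    x = np.asarray(abundances, dtype=float)
    if x.size == 0:
        raise ValueError("empty abundance vector")
    if x.size == 1:
        return np.array([1.0])
    ranks = rankdata(x, method="average")
    return (ranks - 1.0) / (x.size - 1.0)


def normalized_rank_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalized ranks of every entity (columns are samples)."""
    return pd.DataFrame(
        {c: normalized_rank(matrix[c].to_numpy()) for c in matrix.columns},
        index=matrix.index,
    )
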