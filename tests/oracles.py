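"""Independent brute-force reference implementations used only by tests.

These deliberately use different algorithms from the package: the spacer
scanner evaluates every alignment window of every genome with vectorised
mismatch counting (no seeding/short-cuts), and the MED splitter is a plain
string/Counter recursion. They serve as oracles the fast implementations are
checked against.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _windows_hits(genome: str, spacer: str) -> list[tuple[int, int]]:
    """(window_start, mismatches) for every accepted window on one strand."""
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
    L = len(sp)
    if len(g) < L:
        return []
    win = np.lib.stride_tricks.sliding_window_view(g, L)
    mm = win != sp
    m = mm.sum(axis=1)
    five_prime_only = ~mm[:, 2:].any(axis=1)
    ok = (m == 0) | ((m >= 1) & (m <= 2) & five_prime_only & ((L - m) / L >= 0.95))
    return [(int(i), int(m[i])) for i in np.flatnonzero(ok)]


def brute_force_spacer_hits(
    spacers, viral_genomes: dict[str, str]
) -> set[tuple[str, str, int, str, int]]:
    """Every (host, contig, fwd_position, strand, mismatches) hit, both strands."""
    hits = set()
    for contig, genome in viral_genomes.items():
        rc = _revcomp(genome)
        n = len(genome)
        for sp in spacers:
            seq = sp.sequence.upper()
            if set(seq) - set("ACGT"):
                continue
            for w, m in _windows_hits(genome, seq):
                hits.add((sp.source_host_id, contig, w, "+", m))
            for w, m in _windows_hits(rc, seq):
                hits.add((sp.source_host_id, contig, n - (w + len(seq)), "-", m))
    return hits


def _entropy_bits(counter: Counter) -> float:
    total = sum(counter.values())
    h = 0.0
    for c in counter.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def brute_force_med(
    sequences: list[tuple[str, int]],
    entropy_threshold: float = 0.25,
    min_top_count: int = 50,
    min_fraction: float = 0.01,
) -> list[tuple[str, int]]:
    """(template, total_count) per retained ASV, sorted by (-count, template)."""
    if not sequences:
        return []
    parent_total = sum(c for _, c in sequences)
    leaves: list[list[tuple[str, int]]] = []

    def column_entropies(seqs: list[tuple[str, int]]) -> list[float]:
        length = len(seqs[0][0])
        out = []
        for j in range(length):
            counter: Counter = Counter()
            for s, c in seqs:
                counter[s[j]] += c
            out.append(_entropy_bits(counter))
        return out

    def split(seqs: list[tuple[str, int]]):
        ents = column_entropies(seqs)
        if max(ents) <= entropy_threshold:
            leaves.append(seqs)
            return
        j = ents.index(max(ents))  # leftmost maximum
        residues = sorted({s[j] for s, _ in seqs})
        for r in residues:
            split([(s, c) for s, c in seqs if s[j] == r])

    split(list(sequences))
    kept = []
    for leaf in leaves:
        top_seq, top = max(leaf, key=lambda t: (t[1], t[0]))
        total = sum(c for _, c in leaf)
        if top > min_top_count and total / parent_total > min_fraction:
            best = max(leaf, key=lambda t: t[1])
            kept.append((best[0], total))
    kept.sort(key=lambda t: (-t[1], t[0]))
    return kept
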