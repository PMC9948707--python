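"""Genome-based in silico host prediction for viral contigs.

Four evidence routes are combined, mirroring common practice for uncultured
marine viruses:

* **CRISPR spacer matching** — a spacer from a host genome matches a viral
  protospacer at >=95% identity over the whole spacer length, with any
  mismatches (at most two) confined to the spacer's 5' end.
* **tRNA matching** — a viral tRNA identical (100% length and identity) to a
  host tRNA.
* **Nucleotide homology** — the per-virus best BLAST-style hit, accepted only
  above 80% identity over an alignment of >=1,500 bp.
* **gOTU transfer** — a contig inherits the host group of annotated members
  of its genus-level genomic OTU (gOTU), resolved by genomic similarity
  (S_G) when members disagree.

gOTU transfer takes precedence; the three sequence routes must agree with
each other, otherwise the contig is flagged as conflicting and left
unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpacerRecord",
    "SpacerHit",
    "HostAssignment",
    "revcomp",
    "match_spacers",
    "match_trnas",
    "homology_link",
    "assign_gotu",
    "transfer_by_gotu",
    "integrate",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerRecord:
    spacer_id: str
    source_host_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 20:
            raise ValueError("spacers must be at least 20 nt")


@dataclass(frozen=True)
class SpacerHit:
    host_id: str
    contig_id: str
    spacer_id: str
    position: int  # 0-based start on the forward strand of the contig
    strand: str    # "+" or "-"
    mismatches: int


@dataclass
class HostAssignment:
    contig_id: str
    host_group: str | None
    method: str | None  # gotu_transfer / crispr / trna / homology
    evidence_ids: list[str] = field(default_factory=list)
    conflict: bool = False


def _spacer_ok(sequence: str) -> bool:
    return set(sequence) <= set("ACGT")


def _scan_one_strand(spacer: str, genome: str):
    """Seed-and-extend scan of one genome strand for one spacer.

    Any accepted window matches the spacer exactly from its third position
    onward (mismatches are only allowed at the first two 5' positions), so
    exact occurrences of ``spacer[2:]`` enumerate every candidate window.
    Yields (window_start, mismatch_count).
    """
    L = len(spacer)
    tail = spacer[2:]
    seen = set()
    start = genome.find(tail)
    while start != -1:
        w = start - 2
        if w >= 0 and w not in seen:
            seen.add(w)
            m = (genome[w] != spacer[0]) + (genome[w + 1] != spacer[1])
            if m == 0 or (m <= 2 and (L - m) / L >= 0.95):
                yield w, m
        start = genome.find(tail, start + 1)


def match_spacers(
    spacers: list[SpacerRecord], viral_genomes: dict[str, str]
) -> list[SpacerHit]:
    """All spacer-protospacer hits between host spacers and viral genomes.

    Both strands are scanned; a hit requires either a perfect match or 1-2
    mismatches confined to the spacer's 5' end while keeping whole-length
    identity >= 95%. Spacers containing non-ACGT symbols are skipped with a
    warning.
    """
    hits: list[SpacerHit] = []
    for contig, genome in viral_genomes.items():
        genome = genome.upper()
        rc = revcomp(genome)
        n = len(genome)
        for sp in spacers:
            seq = sp.sequence.upper()
            if not _spacer_ok(seq):
                warnings.warn(f"spacer {sp.spacer_id} contains non-ACGT symbols; skipped")
                continue
            for w, m in _scan_one_strand(seq, genome):
                hits.append(SpacerHit(sp.source_host_id, contig, sp.spacer_id, w, "+", m))
            for w, m in _scan_one_strand(seq, rc):
                fwd = n - (w + len(seq))
                hits.append(SpacerHit(sp.source_host_id, contig, sp.spacer_id, fwd, "-", m))
    return hits


def match_trnas(
    host_trnas: dict[str, list[str]], viral_trnas: dict[str, list[str]]
) -> list[tuple[str, str]]:
    """(host, contig) pairs sharing an identical tRNA sequence (either strand)."""
    index: dict[str, set[str]] = {}
    for host, seqs in host_trnas.items():
        for s in seqs:
            s = s.upper()
            index.setdefault(s, set()).add(host)
            index.setdefault(revcomp(s), set()).add(host)
    pairs: set[tuple[str, str]] = set()
    for contig, seqs in viral_trnas.items():
        for s in seqs:
            for host in index.get(s.upper(), ()):
                pairs.add((host, contig))
    return sorted(pairs)


def homology_link(
    alignments: list[tuple[str, str, int, float, float]],
    min_identity: float = 80.0,
    min_length: int = 1_500,
) -> list[tuple[str, str]]:
    """Best-hit (contig -> host) links from tabular alignment records.

    ``alignments`` rows are (contig, host, aln_length, percent_identity,
    bitscore). Per contig only the top-bitscore record is considered, and a
    link is emitted iff identity > ``min_identity`` and length >=
    ``min_length``.
    """
    best: dict[str, tuple[str, str, int, float, float]] = {}
    for rec in alignments:
        contig = rec[0]
        if contig not in best or rec[4] > best[contig][4]:
            best[contig] = rec
    links = []
    for contig, (_, host, length, ident, _) in sorted(best.items()):
        if ident > min_identity and length >= min_length:
            links.append((contig, host))
    return links


def assign_gotu(
    contig_id: str,
    sg_entries: dict[tuple[str, str], float],
    reference_gotus: dict[str, str],
    threshold: float = 0.15,
) -> str:
    """gOTU of the most S_G-similar reference, if that score is strictly >0.15.

    Ties on the best score resolve to the lexicographically smallest reference
    id. Returns "unassigned" when no reference clears the threshold.
    """
    scores = [
        (score, ref)
        for (c, ref), score in sg_entries.items()
        if c == contig_id and ref in reference_gotus
    ]
    if not scores:
        return "unassigned"
    best_score = max(s for s, _ in scores)
    if best_score <= threshold:
        return "unassigned"
    best_ref = min(ref for s, ref in scores if s == best_score)
    return reference_gotus[best_ref]


def transfer_by_gotu(
    contig_id: str,
    gotu_members_hosts: dict[str, str | None],
    sg_entries: dict[tuple[str, str], float],
) -> str | None:
    """Host group inherited from annotated members of the contig's gOTU.

    If every annotated member agrees, that host group is transferred. If they
    disagree, the host of the most S_G-similar annotated member wins. With no
    annotated member, returns None.
    """
    annotated = {m: h for m, h in gotu_members_hosts.items() if h is not None}
    if not annotated:
        return None
    groups = set(annotated.values())
    if len(groups) == 1:
        return groups.pop()
    best_host, best_score = None, -np.inf
    for member, host in sorted(annotated.items()):
        score = sg_entries.get((contig_id, member), sg_entries.get((member, contig_id), -np.inf))
        if score > best_score:
            best_host, best_score = host, score
    return best_host


def integrate(
    contig_ids: list[str],
    gotu_hosts: dict[str, str],
    spacer_hits: list[SpacerHit],
    trna_pairs: list[tuple[str, str]],
    homology_links: list[tuple[str, str]],
    host_taxon: dict[str, str],
) -> dict[str, HostAssignment]:
    """Combine the four evidence routes into one assignment per contig.

    gOTU transfer outranks the sequence-based routes. Among CRISPR, tRNA and
    homology, two routes disagreeing on the host group flags the contig as
    conflicting and leaves it unassigned; agreement (or a single firing
    route) assigns that group. The result is independent of evidence order.
    """
    by_contig: dict[str, dict[str, tuple[str, list[str]]]] = {c: {} for c in contig_ids}

    def add(contig: str, method: str, group: str, ev: str):
        slot = by_contig.setdefault(contig, {})
        if method not in slot:
            slot[method] = (group, [])
        slot[method][1].append(ev)

    for hit in spacer_hits:
        add(hit.contig_id, "crispr", host_taxon[hit.host_id], hit.spacer_id)
    for host, contig in trna_pairs:
        add(contig, "trna", host_taxon[host], f"trna:{host}")
    for contig, host in homology_links:
        add(contig, "homology", host_taxon[host], f"aln:{host}")

    out: dict[str, HostAssignment] = {}
    for contig in contig_ids:
        gotu_host = gotu_hosts.get(contig)
        if gotu_host is not None:
            out[contig] = HostAssignment(contig, gotu_host, "gotu_transfer", ["gotu"])
            continue
        slot = by_contig.get(contig, {})
        groups = {g for g, _ in slot.values()}
        if not slot:
            out[contig] = HostAssignment(contig, None, None)
        elif len(groups) > 1:
            ev = sorted(e for _, evs in slot.values() for e in evs)
            out[contig] = HostAssignment(contig, None, None, ev, conflict=True)
        else:
            # deterministic method label: fixed precedence among agreeing routes
            for method in ("crispr", "trna", "homology"):
                if method in slot:
                    group, ev = slot[method]
                    all_ev = sorted(e for _, evs in slot.values() for e in evs)
                    out[contig] = HostAssignment(contig, group, method, all_ev)
                    break
    return out
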