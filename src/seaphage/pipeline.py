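"""End-to-end orchestration on a synthetic dataset.

Runs the full analysis exactly as it would run on real inputs: sampled
amplicon reads are rarefied and normalised, virome read counts become FPKM
values and are abundance-filtered, host groups are predicted from the
genome features, the cooccurrence screen and transitive pruning are applied,
and the result is scored against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import amplicon, cooccurrence, hostpred, snp, virome
from .simulate import SyntheticDataset, _host_id

__all__ = [
    "predict_hosts",
    "run_cooccurrence",
    "recovery_metrics",
    "entropy_association",
    "CooccurrenceRun",
]


def predict_hosts(ds: SyntheticDataset) -> dict[str, hostpred.HostAssignment]:
    """Host-group assignment for every contig from the planted genome features."""
    g = ds.genomes
    host_taxon = {_host_id(a): t for a, t in ds.truth.asv_taxon.items()}
    gotu_hosts: dict[str, str] = {}
    for contig in g.viral_genomes:
        gotu = hostpred.assign_gotu(contig, g.sg_entries, g.reference_gotus)
        if gotu == "unassigned":
            continue
        members = {
            ref: g.reference_hosts.get(ref)
            for ref, label in g.reference_gotus.items()
            if label == gotu
        }
        transferred = hostpred.transfer_by_gotu(contig, members, g.sg_entries)
        if transferred is not None:
            gotu_hosts[contig] = transferred
    spacer_hits = hostpred.match_spacers(g.spacers, g.viral_genomes)
    trna_pairs = hostpred.match_trnas(g.host_trnas, g.viral_trnas)
    links = hostpred.homology_link(g.alignments)
    return hostpred.integrate(
        list(g.viral_genomes), gotu_hosts, spacer_hits, trna_pairs, links, host_taxon
    )


@dataclass
class CooccurrenceRun:
    asv_rel: pd.DataFrame
    viral_fpkm: pd.DataFrame
    filtered_contigs: list[str]
    assignments: dict[str, hostpred.HostAssignment]
    pairs: pd.DataFrame
    asv_pairs: pd.DataFrame


def run_cooccurrence(ds: SyntheticDataset) -> CooccurrenceRun:
    """Full screen on rarefied amplicon and FPKM-filtered virome data."""
    rarefied = amplicon.rarefy(ds.amplicon_counts, seed=ds.config.rng(20))
    asv_rel = amplicon.to_relative(rarefied)
    viral_fpkm = virome.fpkm(ds.virome_counts, ds.genomes.contig_lengths)
    kept = virome.abundance_filter(viral_fpkm)
    assignments = predict_hosts(ds)
    host_group = {c: a.host_group for c, a in assignments.items()}
    pairs = cooccurrence.screen(
        asv_rel, viral_fpkm.loc[kept], host_group, ds.truth.asv_taxon
    )
    asv_pairs = cooccurrence.asv_asv_pairs(asv_rel)
    pairs = cooccurrence.prune_transitive(pairs, asv_pairs)
    return CooccurrenceRun(asv_rel, viral_fpkm, kept, assignments, pairs, asv_pairs)


def recovery_metrics(run: CooccurrenceRun, ds: SyntheticDataset) -> dict:
    """Recall/precision of planted virus-host pairs and decoy pruning rate."""
    truth_pairs = {(a, c) for c, a in ds.truth.virus_to_host.items()}
    cooc = run.pairs[run.pairs["cooccurring"]]
    found = {(a, c) for a, c in zip(cooc["asv_id"], cooc["contig_id"])}
    tp = len(found & truth_pairs)
    recall = tp / len(truth_pairs) if truth_pairs else float("nan")
    precision = tp / len(found) if found else float("nan")
    sig_unsup = run.pairs[run.pairs["significant"] & ~run.pairs["supported"]]
    decoy_set = {(c, a) for c, a in ds.truth.decoy_pairs}
    decoy_rows = [
        (a, c, pr)
        for a, c, pr in zip(sig_unsup["asv_id"], sig_unsup["contig_id"], sig_unsup["pruned"])
        if (c, a) in decoy_set
    ]
    n_decoy = len(decoy_rows)
    n_pruned = sum(1 for _, _, pr in decoy_rows if pr)
    return {
        "n_planted": len(truth_pairs),
        "n_cooccurring": len(found),
        "true_positives": tp,
        "recall": recall,
        "precision": precision,
        "decoy_edges_significant": n_decoy,
        "decoy_edges_pruned": n_pruned,
        "decoy_prune_rate": n_pruned / n_decoy if n_decoy else float("nan"),
    }


def entropy_association(ds: SyntheticDataset, min_coverage: float = 10.0):
    """(rho, p, table): entropy-abundance association over contig-months."""
    table = snp.entropy_table(ds.allele_counts, min_coverage=min_coverage)
    abund = [
        float(ds.viral_rel.loc[c, m]) for c, m in zip(table["contig"], table["month"])
    ]
    table = table.assign(abundance=abund)
    rho, p = snp.entropy_abundance_association(
        table["avg_entropy"].to_numpy(), table["abundance"].to_numpy()
    )
    return rho, p, table
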