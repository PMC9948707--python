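"""Prokaryotic amplicon processing: rarefaction, abundant ASVs, MED, diversity.

Reads are rarefied to the shallowest sample, converted to relative
abundances, and screened for abundant entities (>=1% in at least one month).
Minimum-entropy decomposition (MED) then splits one OTU's aligned reads into
amplicon sequence variants, and Shannon/richness/evenness summarise a sample.
"""

from seaphage.amplicon import (
    abundant_entities,
    diversity,
    med_decompose,
    rarefy,
    to_relative,
)
from seaphage.simulate import ScenarioConfig, simulate_scenario

ds = simulate_scenario(ScenarioConfig(seed=1))

rarefied = rarefy(ds.amplicon_counts, seed=0)
depth = int(rarefied.sum(axis=0).iloc[0])
rel = to_relative(rarefied)
abundant = abundant_entities(rel, cutoff=0.01)
print(f"rarefied to {depth} reads/sample; "
      f"{len(abundant)}/{rel.shape[0]} ASVs are abundant (>=1% in some month)")

otu, variants = next(iter(ds.amplicon_variants.items()))
asvs = med_decompose(variants, parent_otu=otu)
print(f"\nMED of {otu}: {len(variants)} template variants, "
      f"{sum(c for _, c in variants)} reads ->")
for a in asvs:
    print(f"  {a.asv_id}: {a.count} reads")

profile = diversity(rel.iloc[:, 0])
print(f"\nfirst-month diversity: H'={profile.shannon:.3f} nats, "
      f"richness={profile.richness}, Pielou J={profile.evenness:.3f}")
print("H' is the Shannon entropy of the composition; J=1 would mean all ASVs",
      "equally abundant.")
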