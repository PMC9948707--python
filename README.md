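# seaphage

Analysis tools for monthly time series of marine prokaryotic and viral
communities: who infects whom, how seasonal both communities are, and
whether viral abundance follows host density.

In coastal seawater, most viruses are phages that can only replicate by
encountering their (often strain-specific) host, so infection is
frequency-dependent ("kill-the-winner"): a virus becomes abundant when its
host does. `seaphage` implements the computational side of testing that
picture on paired 16S amplicon + virome monthly observations:

* **Amplicon profiles** — rarefaction, relative abundance, abundant-OTU
  selection (≥1% in some month), minimum-entropy decomposition (MED) of
  aligned reads into amplicon sequence variants (recursive splitting at
  alignment positions with Shannon entropy > 0.25 bits; ASVs kept when
  their top sequence exceeds 50 copies and >1% of the parent OTU), and
  Shannon/richness/Pielou diversity.
* **Virome quantification** — greedy longest-first dereplication at 95%
  ANI, FPKM abundances, genus-level gOTU assignment (genomic similarity
  S_G > 0.15 to the most similar reference), the FPKM > 10 abundance
  filter, and normalized community ranks (0–1).
* **Host prediction** — CRISPR spacer matching (≥95% identity over the
  whole spacer, at most two mismatches confined to the 5′ end), perfect
  tRNA matches, best-hit nucleotide homology (>80% identity over ≥1,500
  bp), gOTU-based transfer, and conflict-aware integration.
* **Seasonality statistics** — Bray–Curtis similarity versus sampling
  interval, season labels, and Spearman-based Mantel / partial Mantel
  permutation tests.
* **Cooccurrence network** — Spearman screen of every (ASV, viral contig)
  pair over shared months, gated at ρ > 0.6, P < 0.01 and
  Benjamini–Hochberg q < 0.05, restricted to pairs supported by host
  prediction, with transitive false-positive pruning, absolute-abundance
  conversion (cell / VLP counts × relative abundance), environmental
  correlations, and normalized-rank-versus-host-density analysis.
* **Dynamics indices** — the *r*-like index (maximum monthly increase of
  an ASV's normalized rank) and *K*-like index (longest run of months
  above 0.1% relative abundance); persistent = K > 12 & r < 0.1,
  temporary = K < 3 & r > 0.5; viral year specificity (>5× between years).
* **SNP entropy** — per-site allele entropy, genome averages gated at >10×
  coverage, and their association with viral abundance.

Because the original sequencing data are too large to carry around, the
package ships a first-class **synthetic community generator**
(`seaphage.simulate`) that emulates an 18-month coastal time series with
planted ground truth: host archetypes (persistent / seasonal / opportunist),
one-to-many virus–host coupling, succession (year-specific) viruses, planted
CRISPR spacers, tRNAs, homologous segments and gOTU links, multinomial read
sampling, and allele counts with a planted diversity–abundance gradient.
Every downstream stage can therefore be scored against a known answer.

## Worked example

`examples/06_cooccurrence_network.py` runs the whole pipeline on the
default synthetic scenario (seed 1) and scores it against the planted
virus–host map:

```
pairs tested              : 2312
significant & supported   : 63
planted pairs             : 68
recall                    : 0.87
precision                 : 0.94
decoy edges significant   : 106, pruned 99% as transitive false positives
median cooccurring viruses per ASV: 2

normalized viral rank by host density bin (median [IQR]):
  host <0.1%  : 0.21 [0.10-0.33]  (n=386)
  host 0.1-1% : 0.49 [0.39-0.60]  (n=308)
  host >1%    : 0.84 [0.75-0.91]  (n=440)
```

Of 2,312 tested ASV–contig pairs, 63 pass the full gate and host-support
filter; 59 of them are true planted pairs (precision 0.94) covering 87% of
the planted infections. The 106 significant-but-unsupported "mirror" edges
(a virus correlating with a same-phase ASV of the wrong taxon) are almost
all removed by transitive pruning. The rank–density table is the
frequency-dependence signature: when a host exceeds 1% of the community its
viruses sit near the top of the viral community (median normalized rank
0.84), while rare hosts' viruses sit near the bottom (0.21).

The other scripts in `examples/` each demonstrate one capability
(simulation, amplicon processing, virome quantification, host prediction,
seasonality, dynamics + SNP entropy) and print a line explaining what the
numbers mean.

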