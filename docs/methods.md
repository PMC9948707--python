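# Methods

This note documents the models and procedures implemented in `seaphage`,
the reasoning behind parameter defaults, and what the synthetic benchmark
does and does not demonstrate.

## Analysis pipeline

### Amplicon side

Counts are rarefied once per sample (multivariate hypergeometric draw, i.e.
subsampling without replacement, with a recorded seed) to the shallowest
sample's depth; a single draw rather than an average of draws is used so
that the downstream matrix is an actual realizable dataset. Abundant
entities are those reaching the cutoff (default 1%) in **at least one**
sample; the boundary is inclusive. The 1% default reflects the usual
coastal argument: at ~10^6 cells/mL, 1% relative abundance corresponds to
~10^4 cells/mL, the minimum host density commonly cited for efficient viral
propagation.

Minimum-entropy decomposition (MED) partitions an alignment of equal-length
reads recursively at the maximum-entropy position while any position
exceeds the entropy threshold, then filters leaves. Numerical choices:

* Entropy is Shannon entropy in **bits** (the oligotyping tradition);
  the 0.25 threshold is interpreted in bits and is configurable.
* Ties between equal maximum-entropy positions split at the **leftmost**
  position (determinism).
* Filters are strict: an ASV is kept iff its most abundant sequence has
  **more than** `min_top_count` (50) copies **and** its reads are **more
  than** `min_fraction` (1%) of the parent OTU's reads. Boundary equality
  discards.
* ASVs are named `<OTU>-<k>` in order of decreasing read count.

Diversity: H′ = −Σ p log p over nonzero proportions (base configurable,
natural log by default), richness = number of nonzero entities, Pielou
J = H′/log(richness), defined as 0 for a single entity.

### Virome side

Dereplication follows the greedy longest-first rule used by common
ANI-clustering tools: contigs are visited by decreasing length (id as a
deterministic tiebreak) and join the first representative with ANI ≥ 95%,
else found a new cluster. The pairwise-ANI map itself is consumed, not
computed.

FPKM[i, s] = count[i, s] / (length_i/10^3) / (mapped_s/10^6), where
`mapped_s` is the per-sample total of the supplied count matrix (reads
mapped to the analysed viral set, not total sequenced reads — relative
abundance "among the analysed viruses"). Community membership requires
FPKM **strictly greater than** 10 in at least one month. gOTU assignment
takes the gOTU of the most S_G-similar reference iff that score is
strictly > 0.15; score ties resolve to the lexicographically smallest
reference id. Normalized rank maps average ranks to [0, 1] with the most
abundant entity at 1 (a single entity gets 1.0).

### Host prediction

* **CRISPR spacers**: a hit requires an alignment window of exactly the
  spacer length (both strands scanned) that either matches perfectly or
  carries one to two mismatches, all located in the first two positions of
  the spacer as written (its 5′ end), while whole-length identity stays
  ≥ 95% (so two mismatches require a spacer of ≥ 40 nt). Both clauses are
  conjunctive. The implementation seeds on exact occurrences of the spacer
  minus its first two positions and verifies the window — any valid hit
  matches exactly from position 3 onward, so the seed scan is exhaustive;
  tests verify equivalence against a full sliding-window scan.
* **tRNAs**: perfect match only — 100% length and 100% identity, either
  strand.
* **Homology**: per virus, only the top-bitscore alignment record is
  considered; it yields a link iff identity > 80% and alignment length
  ≥ 1,500 bp. Alignment records are consumed (tabular BLAST-style input in
  real mode, planted truth in synthetic mode); no aligner is embedded.
* **gOTU transfer**: if all annotated members of a contig's gOTU agree on
  a host group it is transferred; if they disagree, the host of the most
  S_G-similar annotated member wins; with no annotated member nothing is
  assigned.
* **Integration**: gOTU transfer outranks the sequence routes. Among
  CRISPR/tRNA/homology, two routes naming different host groups flag the
  contig as conflicting and leave it unassigned; agreement (or a single
  firing route) assigns. The result is invariant to evidence order.

Host groups are phylum-level labels (class level for Proteobacteria).

### Seasonality

Bray–Curtis similarity (1 − dissimilarity) is computed for every unordered
sample pair and binned by month interval |Δ month_index|; the table reports
mean, SD and pair count per lag (17 … 1 pairs for 18 consecutive months).

Mantel tests correlate the upper triangles of two distance matrices with a
**Spearman-type** rank correlation (Pearson optional), because published
tables report "rho"; p-values are one-sided (greater), estimated by jointly
permuting the rows/columns of one matrix with the add-one estimator
(1 + #{ρ_perm ≥ ρ})/(1 + n_perm). The partial variant rank-transforms the
triangles, residualises both on the control matrix by least squares,
correlates the residuals, and permutes the first matrix with the control
fixed; a matrix fully explained by the control has zero residual variance
and is reported as ρ = 0. Environmental distances are Euclidean on
z-scored variables; "combined" matrices simply use the respective variable
subsets.

### Cooccurrence network

All (ASV, filtered contig) pairs over shared months are screened with
Spearman correlation (vectorised ranks; p from the t approximation, the
same small-sample approximation `scipy.stats.spearmanr` uses). Gates:

* virus–host family: ρ > 0.6 AND p < 0.01 AND BH q < 0.05, one-sided
  positive (viral production tracks host density; anti-correlations are
  not "cooccurrence").
* q is Benjamini–Hochberg within the whole virus–ASV family; ASV–ASV pairs
  (used for pruning) and environmental correlations form separate BH
  families. The environmental gate is two-sided (|ρ| > 0.6).

A significant pair is **cooccurring** only when the contig's predicted host
group equals the ASV's taxon. A significant-but-unsupported pair (A, X) is
pruned as a transitive false positive iff some ASV Y exists with (A, Y)
significant and supported and (X, Y) a significant ASV–ASV pair; supported
pairs are never pruned. Correlations are computed on synchronous months
only — no time-lagged variant — and months where both members are zero are
retained (zeros are informative ranks; ties get average ranks).

Absolute abundance = relative abundance × per-sample cell (or VLP) count;
samples without counts are dropped.

### Dynamics indices

Monthly sampling cannot identify growth rate r or carrying capacity K, so
two proxies classify temporal behaviour: the *r*-like index is the maximum
month-over-month **increase** of the ASV's normalized community rank
(floored at 0, so it lives in [0, 1]); the *K*-like index is the longest
run of consecutive months strictly above 0.1% relative abundance (0 is
allowed for never-abundant series). Ranks are normalized among **all**
ASVs of the supplied matrix each month (configurable by passing a subset).
Labels: persistent iff K > 12 and r < 0.1; temporary iff K < 3 and
r > 0.5; otherwise intermediate. Year specificity compares abundance
totals over the two sampled calendar years: a virus is year-specific iff
one total strictly exceeds five times the other.

### SNP entropy

Per-site entropy is Shannon entropy of the A/C/G/T frequencies (natural
log by default, base-2 optional). The genome average for one contig-month
is the arithmetic mean of site entropies over sites with nonzero depth,
reported only when the **mean** coverage strictly exceeds 10×; sites with
zero depth are excluded rather than counted as zero. The
entropy–abundance association is a Spearman correlation across
contig-months, optionally stratified by predicted host group.

## Synthetic community generator

The generator's defaults define the package's reference study: 18
consecutive monthly samples (March 2015 – August 2016), 34 prokaryotic
ASVs, 68 viral contigs (one to three per host), with sequencing depths of
50–80k amplicon reads and 10^6 virome reads per sample — within the ranges
typical of MiSeq amplicon and coastal virome studies.

**Host archetypes.** Log raw weights (arbitrary units; shares emerge by
monthly renormalisation) follow:

* *persistent* (10 ASVs; Alphaproteobacteria / Thaumarchaeota /
  Nitrospirae): geometric baseline ladder 20 × 0.75^k (top ASV ≈ 20–25% of
  the community, bottom ≈ 1.5%) with a weak annual cosine (amplitude
  0.32–0.40 on the log scale, i.e. ~2× peak-to-trough) whose peak phases
  are spread evenly over the year. Persistently dominant populations such
  as SAR11 do vary severalfold annually while staying abundant; the even
  phase spread keeps same-taxon persistents out of phase (no spurious
  supported correlations) and makes the community's pairwise dissimilarity
  follow the annual |sin(π·lag/12)| law, bottoming at 6 months.
* *seasonal* (6 spring-phased peaking in May, 6 summer-phased peaking in
  June; one taxon each): period-12 sinusoid on log weight, amplitude
  1.0–1.5 (≈ 7–20× annual range), peak weight 0.2–0.4 units (≈ 0.3–0.7% of
  the community at peak). Same-peak ASVs always belong to different taxa:
  their viruses correlate with the mirror ASV, planting the
  unsupported-but-correlated decoy edges that transitive pruning must
  remove. Centring both cohorts on the May/June axis keeps the maximum
  community contrast at the 6-month interval.
* *opportunist* (12 ASVs; Epsilonproteobacteria, Betaproteobacteria,
  Firmicutes, Fusobacteria — groups not used by the other archetypes, so
  archetype mixing cannot fake host support): an erratic low baseline
  (0.008–0.02 units, ≈ 0.02–0.04%) with a sharp bloom (4.3–4.7 units,
  ≈ 6–8% of the community) recurring at a preferred calendar month,
  realised as one or two bloom months in the 18-month window. Preferred
  months are spread evenly over the year (season-faithful blooms, e.g.
  summer Vibrio-like behaviour) so bloom turnover contributes annual
  signal rather than arbitrary between-pair noise.

**Noise.** Multiplicative lognormal noise with a Taylor-law scaling:
σ_i(t) = σ₀ / w_i(t)^0.5 capped at 0.35, with σ₀ = 0.04 at one weight
unit. Large populations (and bloom peaks) fluctuate little in relative
terms; rare baselines are strongly erratic. This one mechanism yields
steady dominants, noisy rare opportunists whose viruses still have a
trajectory to track, and stable pairwise community similarities.
Setting `noise_sigma = 0` makes the generator fully deterministic.

**Virus coupling.** Each virus's raw abundance is its host's relative
abundance at t − lag (lag 0 by default, 1 supported), times a per-virus
burst factor drawn log-uniform in [0.2, 5] (burst sizes in the sea span
roughly 6–300; only the spread matters after renormalisation), times
lognormal tracking noise (σ = 0.6 × σ₀). Columns are renormalised, so
viral abundances are compositional like the real FPKM shares.
One consequence: with unequal bursts the viral denominator wobbles, so
planted rank correlations are exactly 1 at zero noise only when the
denominator is constant (e.g. one virus per host with equal bursts); under
the default burst lottery they remain ≥ 0.9.

**Succession (year-specific) viruses.** 25% of seasonal-host viruses are
boosted by a factor 8 (comfortably beyond the 5× year-specificity rule) in
one randomly chosen calendar year, emulating the year-to-year replacement
of dominant bloom viruses. Succession is confined to the low-mass seasonal
band deliberately: gating a dominant virus would step the compositional
denominator of the whole viral community at the calendar-year boundary and
contaminate every other virus's trajectory. These viruses are expected
*misses* of the cooccurrence screen — the year gate breaks their host
correlation, exactly the phenomenon that motivates looking beyond
cooccurrence.

**Genome features.** One evidence route per virus, cycled
(gOTU / CRISPR / tRNA / homology): a 25–40-nt protospacer copied into a
host spacer record, perturbed by 0–2 substitutions confined to the spacer's
5′ end and never violating the 95% identity rule; an identical 70–90-nt
tRNA in both genomes; a 1,500–2,500-bp shared segment mutated to a
recorded identity of 82–95% (requesting < 80% is rejected as inconsistent
truth); or an S_G entry (0.2–0.6) to an annotated reference genome.
Decoy spacers and tRNAs that match nothing, and sub-threshold alignment
records (1,200 bp @ 95%; 2,000 bp @ 75%), are planted alongside. The
alphabet is strict A/C/G/T so the exact matchers are exercised without
ambiguity-code rules.

**Allele counts.** Per contig-month, sequencing depth is
`coverage_scale` (3,000) × relative abundance; each of 60 sites draws a
minor-allele count from a binomial whose expected fraction rises linearly
(0.02 → 0.30) with the contig-month's abundance rank, planting a positive
diversity–abundance gradient with realistic binomial sampling noise.

**Amplicon variants.** Per OTU, 1–4 equal-length template variants
differing only at planted positions, with recorded copy numbers (80–1,200)
— the ground truth for MED.

**Determinism.** Every stage draws from its own seeded substream, so a
`ScenarioConfig` (including its seed) reproduces byte-identical outputs
regardless of which stages are invoked.

### What the benchmark does and does not show

The generator plants exactly the structures the pipeline looks for —
period-12 seasonality, monotone virus–host coupling, taxonomically clean
host evidence, a linear diversity–abundance gradient — plus controlled
confounders (mirror decoys, succession viruses, decoy genome features,
compositional distortion, multinomial sampling noise). Passing tests
therefore show that the implementation detects what it claims to detect
and rejects the planted confounders at the stated thresholds. They do not
show that real communities satisfy these assumptions: real time series
have irregular sampling, unmodelled lags between host and virus peaks,
broad-host-range viruses, partial and erroneous host databases,
sequencing error, chimeras, and taxa whose dynamics fit none of the four
archetypes. Real-data conclusions still require the original sensitivity
analyses (absolute-abundance cross-checks, per-taxon breakdowns).

## Problem sizes

Default test and acceptance runs use the reference scenario (34 ASVs, 68
contigs, 18 months), 500 null simulations with 199 permutations each for
Mantel calibration, 100 shuffles for the entropy null, and the
20 × 50-kb × 200-spacer oracle-equivalence scan — all chosen to exercise
the full algorithms at a scale a laptop handles in minutes.

## Known limitations

* Spearman on synchronous months only; delayed correlations are invisible.
* The q-value procedure is fixed to Benjamini–Hochberg.
* The spacer matcher's "5′ end" is the spacer's own 5′ end; protospacer
  orientation conventions differ between tools (configurable seed length).
* Mantel permutations are plain row/column permutations; no restricted or
  stratified permutation schemes.
* The generator's archetypes are stylised; it does not simulate sequencing
  error, chimeras, or read-level artefacts (counts are exact multinomial
  draws), and FASTQ emission is out of scope.
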