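"""Synthetic monthly virus-host community generator with planted ground truth.

The generator emulates the structure of a coastal marine time series sampled
monthly for 18 months: a prokaryotic community of amplicon sequence variants
(ASVs) drawn from a few temporal archetypes, and a viral community whose
members each track the abundance of their single true host ASV
(frequency-dependent, "kill-the-winner" coupling). Every stochastic choice is
recorded in a :class:`PlantedTruth` object so that downstream inference
(cooccurrence screening, host prediction, dynamics classification, SNP
entropy) can be scored against a known answer.

Archetypes
----------
persistent
    Dominant baseline with a weak annual oscillation (evenly spread peak
    phases), always well above 0.1% of the community (SAR11-like behaviour).
seasonal_summer / seasonal_spring
    Period-12 sinusoid on log-abundance peaking in a summer (June) or spring
    (May) month (Synechococcus- / Bacteroidetes-like blooms).
opportunist
    Very low erratic baseline with a sharp recurring bloom at a preferred
    calendar month (Vibrio-like), realised as 1-2 bloom months per series.

Within each seasonal archetype, ASVs of *different* taxa deliberately share a
peak month. Viruses of one such ASV are then strongly correlated with the
mirror ASV of the other taxon, planting "unsupported-but-correlated" decoy
edges that the transitive pruning step of the cooccurrence module is expected
to remove.

All abundances are compositional: archetype trajectories are built on raw
log-weights, perturbed by multiplicative lognormal noise, and renormalised per
month, so columns always sum to one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "PlantedTruth",
    "GenomeSet",
    "SyntheticDataset",
    "build_truth",
    "simulate_host_dynamics",
    "simulate_viral_dynamics",
    "sample_reads",
    "generate_genomes",
    "generate_site_allele_counts",
    "generate_amplicon_variants",
    "sample_metadata",
    "simulate_scenario",
]

SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

# Taxon pools per archetype. Host groups are phylum-level labels (class level
# for Proteobacteria), the resolution at which host prediction operates.
# Within a seasonal archetype each taxon appears once, and taxa are paired up
# on a shared peak month: the same-phase different-taxon "mirror" ASVs plant
# unsupported-but-correlated decoy edges for the pruning step, while no two
# same-taxon ASVs share a seasonal phase (which would fake supported pairs).
PERSISTENT_TAXA = ("Alphaproteobacteria", "Thaumarchaeota", "Nitrospirae")
SUMMER_TAXA = ("Cyanobacteria", "Gammaproteobacteria", "Actinobacteria",
               "Euryarchaeota", "SAR406", "Chloroflexi")
SUMMER_PEAKS = (6, 6, 6, 6, 6, 6)
SPRING_TAXA = ("Bacteroidetes", "Deltaproteobacteria", "Verrucomicrobia",
               "Planctomycetes", "Acidobacteria", "Nitrospinae")
SPRING_PEAKS = (5, 5, 5, 5, 5, 5)
OPPORTUNIST_TAXA = ("Epsilonproteobacteria", "Betaproteobacteria", "Firmicutes", "Fusobacteria")

ALPHABET = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study.

    The defaults define the package's reference scenario: 18 consecutive
    monthly samples starting March 2015; 34 host ASVs (10 persistent, 6 + 6
    seasonal, 12 opportunist); one to three viruses per host; synchronous
    (lag-0) frequency-dependent coupling; multiplicative lognormal noise
    whose relative size shrinks with population size (Taylor-law scaling).
    """

    n_months: int = 18
    start_year: int = 2015
    start_month: int = 3
    archetype_mix: dict[str, int] = field(
        default_factory=lambda: {
            "persistent": 10,
            "seasonal_summer": 6,
            "seasonal_spring": 6,
            "opportunist": 12,
        }
    )
    viruses_per_host: tuple[int, int] = (1, 3)
    coupling_lag: int = 0
    noise_sigma: float = 0.04        # iid lognormal sigma at 1 unit of raw weight
    viral_sigma: float | None = None # virus-around-host sigma; None -> 0.6x noise_sigma
    noise_exponent: float = 0.5      # Taylor-law scaling: sigma_i ~ weight^-exponent
    noise_sigma_cap: float = 0.35
    persistent_amplitude: tuple[float, float] = (0.32, 0.40)
    seasonal_amplitude: tuple[float, float] = (0.7, 1.1)
    seasonal_peak_weight: tuple[float, float] = (0.2, 0.4)
    bloom_weight: tuple[float, float] = (4.3, 4.7)
    total_cells_per_ml: float = 1e6
    total_vlp_per_ml: float = 1e7
    amplicon_depth_range: tuple[int, int] = (50_000, 80_000)
    virome_depth: int = 1_000_000
    succession_fraction: float = 0.25   # fraction of seasonal-host viruses
    year_gate: float = 8.0           # >5x between-year factor for succession viruses
    # genome feature parameters
    host_genome_length: int = 6_000
    viral_genome_length: tuple[int, int] = (10_500, 30_000)
    spacer_length: tuple[int, int] = (25, 40)
    trna_length: tuple[int, int] = (70, 90)
    homolog_length: tuple[int, int] = (1_500, 2_500)
    homolog_identity: tuple[float, float] = (82.0, 95.0)
    # allele-count generator
    sites_per_contig: int = 60
    coverage_scale: float = 3_000.0
    minor_allele_range: tuple[float, float] = (0.02, 0.30)
    seed: int = 0

    def __post_init__(self):
        if self.n_months < 2:
            raise ValueError("n_months must be at least 2")
        if any(v < 0 for v in self.archetype_mix.values()):
            raise ValueError("archetype counts must be nonnegative")
        if self.coupling_lag >= self.n_months:
            raise ValueError("coupling_lag must be smaller than n_months")
        if self.coupling_lag not in (0, 1):
            raise ValueError("coupling_lag must be 0 or 1")

    @property
    def n_host_asvs(self) -> int:
        return sum(self.archetype_mix.values())

    @property
    def effective_viral_sigma(self) -> float:
        return 0.6 * self.noise_sigma if self.viral_sigma is None else self.viral_sigma

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([self.seed, stream])

    def calendar(self) -> tuple[np.ndarray, np.ndarray]:
        """(calendar_month, year) arrays for the sampled months."""
        idx = np.arange(self.n_months)
        months = (self.start_month - 1 + idx) % 12 + 1
        years = self.start_year + (self.start_month - 1 + idx) // 12
        return months, years


@dataclass
class PlantedTruth:
    """Machine-readable ground truth accompanying a generated dataset."""

    virus_to_host: dict[str, str]
    asv_archetype: dict[str, str]
    asv_taxon: dict[str, str]
    asv_params: dict[str, dict]
    burst_factors: dict[str, float]
    evidence_type: dict[str, str]          # contig -> gotu/crispr/trna/homology
    succession_year: dict[str, int]        # contig -> favoured calendar year
    decoy_pairs: list[tuple[str, str]]     # (contig, mirror ASV of another taxon)
    planted_spacers: list[tuple[str, str, int]] = field(default_factory=list)
    planted_trnas: list[tuple[str, str, str]] = field(default_factory=list)
    planted_homologs: list[tuple[str, str, int, float]] = field(default_factory=list)
    asv_variable_positions: dict[str, list[int]] = field(default_factory=dict)
    variant_counts: dict[str, list[int]] = field(default_factory=dict)

    def host_group_of(self, contig: str) -> str:
        return self.asv_taxon[self.virus_to_host[contig]]

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["decoy_pairs"] = [list(p) for p in self.decoy_pairs]
        return d


def _plan_community(config: ScenarioConfig) -> list[dict]:
    """Deterministic per-ASV archetype parameters (taxon, baseline, phase)."""
    rng = config.rng(1)
    plan: list[dict] = []
    counters = {"persistent": 0, "seasonal_summer": 0, "seasonal_spring": 0, "opportunist": 0}
    order = ["persistent", "seasonal_summer", "seasonal_spring", "opportunist"]
    i = 0
    for arch in order:
        for _ in range(config.archetype_mix.get(arch, 0)):
            k = counters[arch]
            counters[arch] += 1
            asv = f"ASV{i + 1}"
            i += 1
            entry = {"asv": asv, "archetype": arch}
            if arch == "persistent":
                # geometrically spaced baselines well above the seasonal band
                # (rank order among persistents is stable against noise swaps)
                # with a WEAK annual oscillation: persistently dominant
                # populations still vary severalfold over a year, and that
                # oscillation both drives community seasonality and gives
                # their viruses a signal to track. Peak phases are spread
                # evenly so no two same-taxon persistents oscillate in phase.
                n_pers = config.archetype_mix.get("persistent", 0)
                entry["taxon"] = PERSISTENT_TAXA[k % len(PERSISTENT_TAXA)]
                entry["base_weight"] = 18.0 * 0.75**k
                entry["amplitude"] = float(rng.uniform(*config.persistent_amplitude))
                entry["peak_month"] = 1 + (k * 12) // max(n_pers, 1) % 12
            elif arch in ("seasonal_summer", "seasonal_spring"):
                taxa = SUMMER_TAXA if arch == "seasonal_summer" else SPRING_TAXA
                peaks = SUMMER_PEAKS if arch == "seasonal_summer" else SPRING_PEAKS
                lo_w, hi_w = config.seasonal_peak_weight
                entry["taxon"] = taxa[k % len(taxa)]
                entry["peak_month"] = peaks[k % len(peaks)]
                entry["peak_weight"] = float(np.exp(rng.uniform(np.log(lo_w), np.log(hi_w))))
                entry["amplitude"] = float(rng.uniform(*config.seasonal_amplitude))
            else:  # opportunist
                lo_b, hi_b = config.bloom_weight
                entry["taxon"] = OPPORTUNIST_TAXA[k % len(OPPORTUNIST_TAXA)]
                entry["base_weight"] = float(np.exp(rng.uniform(np.log(0.008), np.log(0.02))))
                entry["bloom_weight"] = float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))
                # blooms recur at a preferred calendar month (season-faithful
                # opportunists, e.g. summer Vibrio), realised wherever those
                # months appear in the sampling window. Preferred months are
                # spread evenly over the year so blooms do not pile up in one
                # season, and no two same-taxon opportunists share one.
                months_cal, _ = config.calendar()
                n_opp = config.archetype_mix.get("opportunist", 1)
                pref = 1 + (k * 12) // max(n_opp, 1) % 12
                entry["bloom_calendar_months"] = [pref]
                entry["bloom_months"] = sorted(
                    int(t) for t in range(config.n_months)
                    if months_cal[t] in entry["bloom_calendar_months"]
                )
            plan.append(entry)
    return plan


def _log_weight_track(entry: dict, config: ScenarioConfig) -> np.ndarray:
    """Noise-free log raw weight of one ASV across the sampled months."""
    months, _ = config.calendar()
    arch = entry["archetype"]
    if arch == "persistent":
        # weak annual oscillation around a dominant baseline: persistently
        # abundant populations still vary severalfold over the year, and the
        # evenly spread peak phases make the community's pairwise
        # dissimilarity follow the annual |sin(pi*lag/12)| law, bottoming at
        # the 6-month interval
        a, peak = entry["amplitude"], entry["peak_month"]
        phase = 2.0 * np.pi * (months - peak) / 12.0
        return math.log(entry["base_weight"]) + a * np.cos(phase)
    if arch in ("seasonal_summer", "seasonal_spring"):
        a, peak = entry["amplitude"], entry["peak_month"]
        phase = 2.0 * np.pi * (months - peak) / 12.0
        return math.log(entry["peak_weight"]) - a + a * np.cos(phase)
    track = np.full(config.n_months, math.log(entry["base_weight"]))
    track[list(entry["bloom_months"])] = math.log(entry["bloom_weight"])
    return track


def simulate_host_dynamics(config: ScenarioConfig) -> pd.DataFrame:
    """Relative abundance matrix (ASVs x months) of the prokaryotic community.

    Seasonal forcing acts on log raw weight (period-12 sinusoid) before
    renormalisation; iid multiplicative lognormal noise with ``noise_sigma``
    is applied per ASV and month. Columns sum to one.
    """
    plan = _plan_community(config)
    if not plan:
        raise ValueError("archetype_mix is empty")
    rng = config.rng(2)
    rows = []
    for entry in plan:
        logw = _log_weight_track(entry, config)
        # Demographic noise follows a Taylor-law scaling: the relative
        # (lognormal) fluctuation of a population shrinks with its current
        # size, so dominant populations (and bloom peaks) are steady while
        # rare baselines are erratic -- and that erratic trajectory is
        # exactly what the viruses of rare hosts track.
        sigma = np.minimum(
            config.noise_sigma / np.exp(logw) ** config.noise_exponent,
            config.noise_sigma_cap,
        )
        noise = rng.normal(0.0, 1.0, size=config.n_months) * sigma
        rows.append(np.exp(logw + noise))
    raw = np.vstack(rows)
    rel = raw / raw.sum(axis=0, keepdims=True)
    cols = [f"M{t:02d}" for t in range(config.n_months)]
    return pd.DataFrame(rel, index=[e["asv"] for e in plan], columns=cols)


def build_truth(config: ScenarioConfig) -> PlantedTruth:
    """Assign viruses to hosts and plan all planted genome/sequence features."""
    plan = _plan_community(config)
    rng = config.rng(3)
    lo, hi = config.viruses_per_host
    virus_to_host: dict[str, str] = {}
    burst: dict[str, float] = {}
    evidence: dict[str, str] = {}
    evidence_cycle = ("gotu", "crispr", "trna", "homology")
    v = 0
    for entry in plan:
        n_vir = int(rng.integers(lo, hi + 1))
        for _ in range(n_vir):
            contig = f"vOTU{v + 1:03d}"
            virus_to_host[contig] = entry["asv"]
            # burst-size spread without absolute calibration (log-uniform)
            burst[contig] = float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
            evidence[contig] = evidence_cycle[v % 4]
            v += 1
    _, years = config.calendar()
    year_values = sorted(set(int(y) for y in years))
    # year-specific (succession) viruses belong to seasonal hosts: dominant
    # members of a recurring bloom differ between years. Restricting the year
    # gate to the low-mass seasonal band keeps the viral community total free
    # of artificial steps at calendar-year boundaries.
    by_asv_arch = {e["asv"]: e["archetype"] for e in plan}
    eligible = [c for c, a in virus_to_host.items()
                if by_asv_arch[a].startswith("seasonal")]
    n_succ = int(round(config.succession_fraction * len(eligible)))
    succession: dict[str, int] = {}
    if len(year_values) >= 2 and n_succ:
        chosen = rng.choice(len(eligible), size=n_succ, replace=False)
        for j in chosen:
            succession[eligible[int(j)]] = int(year_values[int(rng.integers(len(year_values)))])

    by_asv = {e["asv"]: e for e in plan}
    decoys: list[tuple[str, str]] = []
    for contig, host in virus_to_host.items():
        e = by_asv[host]
        if e["archetype"].startswith("seasonal"):
            for other in plan:
                if (
                    other["asv"] != host
                    and other["archetype"] == e["archetype"]
                    and other.get("peak_month") == e["peak_month"]
                    and other["taxon"] != e["taxon"]
                ):
                    decoys.append((contig, other["asv"]))
    return PlantedTruth(
        virus_to_host=virus_to_host,
        asv_archetype={e["asv"]: e["archetype"] for e in plan},
        asv_taxon={e["asv"]: e["taxon"] for e in plan},
        asv_params={e["asv"]: {k: v for k, v in e.items() if k != "asv"} for e in plan},
        burst_factors=burst,
        evidence_type=evidence,
        succession_year=succession,
        decoy_pairs=decoys,
    )


def simulate_viral_dynamics(
    hosts: pd.DataFrame, truth: PlantedTruth, config: ScenarioConfig
) -> pd.DataFrame:
    """Relative abundance matrix (contigs x months) of the viral community.

    Each virus's raw abundance is its host's relative abundance at
    ``t - coupling_lag`` (clamped at the first month) times a per-virus burst
    factor and lognormal noise; succession viruses are additionally boosted by
    ``year_gate`` in their favoured calendar year. Columns are renormalised to
    sum to one.
    """
    missing = {h for h in truth.virus_to_host.values()} - set(hosts.index)
    if missing:
        raise ValueError(f"hosts matrix lacks rows for true hosts: {sorted(missing)}")
    rng = config.rng(4)
    n = hosts.shape[1]
    _, years = config.calendar()
    t_src = np.clip(np.arange(n) - config.coupling_lag, 0, None)
    rows = []
    for contig, host in truth.virus_to_host.items():
        track = hosts.loc[host].to_numpy()[t_src] * truth.burst_factors[contig]
        track = track * np.exp(rng.normal(0.0, config.effective_viral_sigma, size=n))
        fav = truth.succession_year.get(contig)
        if fav is not None:
            track = np.where(years == fav, track * config.year_gate, track)
        rows.append(track)
    raw = np.vstack(rows)
    rel = raw / raw.sum(axis=0, keepdims=True)
    return pd.DataFrame(rel, index=list(truth.virus_to_host), columns=hosts.columns)


def sample_reads(
    rel: pd.DataFrame, depths, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Multinomial read sampling of a relative abundance matrix.

    ``depths`` is a scalar or one count per sample; each column is one
    multinomial draw, so column sums equal the stated depths exactly.
    """
    depths = np.broadcast_to(np.asarray(depths, dtype=np.int64), (rel.shape[1],))
    if (depths < 0).any():
        raise ValueError("read depths must be nonnegative")
    cols = rel.to_numpy()
    if not np.allclose(cols.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("columns of a relative matrix must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.column_stack(
        [rng.multinomial(int(d), p / p.sum()) for d, p in zip(depths, cols.T)]
    )
    return pd.DataFrame(counts, index=rel.index, columns=rel.columns)


# ---------------------------------------------------------------------------
# genome features


@dataclass
class GenomeSet:
    """Host/viral genomes plus the sequence features host prediction consumes."""

    host_genomes: dict[str, str]
    viral_genomes: dict[str, str]
    spacers: list  # SpacerRecord-compatible tuples handled by hostpred
    host_trnas: dict[str, list[str]]
    viral_trnas: dict[str, list[str]]
    alignments: list[tuple[str, str, int, float, float]]
    sg_entries: dict[tuple[str, str], float]
    reference_hosts: dict[str, str]
    reference_gotus: dict[str, str]
    contig_lengths: dict[str, int]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=length)])


def _host_id(asv: str) -> str:
    return f"host_{asv}"


def generate_genomes(truth: PlantedTruth, config: ScenarioConfig) -> GenomeSet:
    """Emit synthetic genomes with planted host-prediction features.

    One evidence route is planted per virus (cycled): a CRISPR spacer copied
    from the viral genome (optionally perturbed by 1-2 substitutions confined
    to its 5' end, never breaking the 95% identity rule), an identical tRNA, a
    long (>=1,500 bp) homologous segment of recorded identity, or a genomic
    similarity (S_G > 0.15) link to an annotated reference genome. Decoy
    spacers, tRNAs and sub-threshold alignments that must NOT produce hits are
    planted alongside.
    """
    lo_id, hi_id = config.homolog_identity
    if lo_id < 80.0:
        raise ValueError("positive homolog identity below 80% is inconsistent truth")
    rng = config.rng(5)
    from .hostpred import SpacerRecord  # local import to avoid cycle

    hosts = sorted(set(truth.virus_to_host.values()), key=lambda a: int(a[3:]))
    host_genomes = {_host_id(a): _random_seq(rng, config.host_genome_length) for a in hosts}
    viral_genomes: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    for contig in truth.virus_to_host:
        length = int(rng.integers(*config.viral_genome_length))
        viral_genomes[contig] = _random_seq(rng, length)
        contig_lengths[contig] = length

    spacers: list[SpacerRecord] = []
    host_trnas: dict[str, list[str]] = {h: [] for h in host_genomes}
    viral_trnas: dict[str, list[str]] = {c: [] for c in viral_genomes}
    alignments: list[tuple[str, str, int, float, float]] = []
    sg_entries: dict[tuple[str, str], float] = {}
    reference_hosts: dict[str, str] = {}
    reference_gotus: dict[str, str] = {}
    n_spacer = 0

    for contig, asv in truth.virus_to_host.items():
        hid = _host_id(asv)
        genome = viral_genomes[contig]
        route = truth.evidence_type[contig]
        if route == "crispr":
            length = int(rng.integers(*config.spacer_length))
            off = int(rng.integers(0, len(genome) - length))
            proto = genome[off : off + length]
            # up to 2 SNPs at the spacer 5' end, within the 95% identity bound
            max_snps = min(2, int(length * 0.05))
            n_snps = int(rng.integers(0, max_snps + 1))
            spacer = list(proto)
            for pos in range(n_snps):
                choices = [b for b in "ACGT" if b != spacer[pos]]
                spacer[pos] = choices[int(rng.integers(3))]
            n_spacer += 1
            spacers.append(SpacerRecord(f"sp{n_spacer:03d}", hid, "".join(spacer)))
            truth.planted_spacers.append((hid, contig, off))
        elif route == "trna":
            length = int(rng.integers(*config.trna_length))
            seq = _random_seq(rng, length)
            host_trnas[hid].append(seq)
            viral_trnas[contig].append(seq)
            off = int(rng.integers(0, len(genome) - length))
            viral_genomes[contig] = genome[:off] + seq + genome[off + length :]
            truth.planted_trnas.append((hid, contig, seq))
        elif route == "homology":
            length = int(rng.integers(*config.homolog_length))
            ident = float(rng.uniform(lo_id, hi_id))
            off = int(rng.integers(0, len(genome) - length))
            segment = list(genome[off : off + length])
            n_mut = int(round(length * (1.0 - ident / 100.0)))
            mut_pos = rng.choice(length, size=n_mut, replace=False)
            for p in mut_pos:
                choices = [b for b in "ACGT" if b != segment[p]]
                segment[p] = choices[int(rng.integers(3))]
            hg = host_genomes[hid]
            hoff = int(rng.integers(0, len(hg) - length)) if len(hg) > length else 0
            host_genomes[hid] = hg[:hoff] + "".join(segment) + hg[hoff + length :]
            realized = 100.0 * (length - n_mut) / length
            alignments.append((contig, hid, length, realized, 2.0 * length * realized / 100.0))
            truth.planted_homologs.append((contig, hid, length, realized))
        else:  # gotu
            ref = f"REF_{contig}"
            gotu = f"G{1 + int(contig[4:]) % 40:03d}"
            sg_entries[(contig, ref)] = float(rng.uniform(0.2, 0.6))
            reference_hosts[ref] = truth.asv_taxon[asv]
            reference_gotus[ref] = gotu

    # decoys: one random spacer and tRNA per host, plus sub-threshold alignments
    virus_blob = "|".join(viral_genomes.values())
    from .hostpred import revcomp

    for hid in host_genomes:
        while True:
            length = int(rng.integers(*config.spacer_length))
            seq = _random_seq(rng, length)
            if seq[2:] not in virus_blob and revcomp(seq)[:-2] not in virus_blob:
                break
        n_spacer += 1
        spacers.append(SpacerRecord(f"sp{n_spacer:03d}", hid, seq))
        host_trnas[hid].append(_random_seq(rng, int(rng.integers(*config.trna_length))))
    decoy_contigs = list(truth.virus_to_host)[:4]
    for i, contig in enumerate(decoy_contigs):
        hid = _host_id(sorted(hosts)[i % len(hosts)])
        if i % 2 == 0:
            alignments.append((contig, hid, 1_200, 95.0, 1_200.0))  # too short
        else:
            alignments.append((contig, hid, 2_000, 75.0, 1_500.0))  # too divergent

    return GenomeSet(
        host_genomes=host_genomes,
        viral_genomes=viral_genomes,
        spacers=spacers,
        host_trnas=host_trnas,
        viral_trnas=viral_trnas,
        alignments=alignments,
        sg_entries=sg_entries,
        reference_hosts=reference_hosts,
        reference_gotus=reference_gotus,
        contig_lengths=contig_lengths,
    )


def generate_site_allele_counts(viral: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Per-site allele counts planting a positive diversity-abundance trend.

    Sequencing depth of a contig-month scales with its relative abundance
    (``coverage_scale`` x relative abundance); the expected minor-allele
    fraction rises monotonically with the contig-month's abundance rank, so
    the downstream entropy-abundance correlation is planted positive. Returns
    a long-format frame (contig, month, position, A, C, G, T).
    """
    rng = config.rng(6)
    vals = viral.to_numpy()
    order = vals.ravel().argsort().argsort().reshape(vals.shape)  # dense-ish rank
    u = order / max(order.size - 1, 1)
    lo, hi = config.minor_allele_range
    records = []
    bases = "ACGT"
    for i, contig in enumerate(viral.index):
        for j, month in enumerate(viral.columns):
            depth = int(round(config.coverage_scale * vals[i, j]))
            if depth <= 0:
                continue
            maf = lo + (hi - lo) * u[i, j]
            major = int(rng.integers(4))
            minor = (major + 1 + int(rng.integers(3))) % 4
            site_f = maf * rng.uniform(0.3, 1.0, size=config.sites_per_contig)
            minor_counts = rng.binomial(depth, site_f)
            for pos, mc in enumerate(minor_counts):
                row = {"contig": contig, "month": month, "position": pos + 1,
                       "A": 0, "C": 0, "G": 0, "T": 0}
                row[bases[major]] = depth - int(mc)
                row[bases[minor]] += int(mc)
                records.append(row)
    return pd.DataFrame.from_records(
        records, columns=["contig", "month", "position", "A", "C", "G", "T"]
    )


def generate_amplicon_variants(
    truth: PlantedTruth, config: ScenarioConfig, n_otus: int = 6,
    template_length: int = 250,
) -> dict[str, list[tuple[str, int]]]:
    """Aligned per-OTU read sets made of 1-4 template variants.

    Each OTU's reads are exact copies of its templates, which differ only at
    the planted variable positions; variant copy numbers are recorded in the
    truth object so minimum-entropy decomposition can be scored exactly.
    """
    rng = config.rng(7)
    out: dict[str, list[tuple[str, int]]] = {}
    for o in range(n_otus):
        otu = f"OTU{o + 1}"
        base = _random_seq(rng, template_length)
        n_var = int(rng.integers(1, 5))
        n_pos = max(n_var - 1, 0)
        positions = sorted(int(p) for p in rng.choice(template_length, n_pos, replace=False))
        templates = [base]
        for k in range(1, n_var):
            t = list(base)
            for p in positions[: k]:
                choices = [b for b in "ACGT" if b != base[p]]
                t[p] = choices[int(rng.integers(3))]
            templates.append("".join(t))
        counts = sorted(
            (int(c) for c in rng.integers(80, 1_200, size=n_var)), reverse=True
        )
        out[otu] = list(zip(templates, counts))
        truth.asv_variable_positions[otu] = positions
        truth.variant_counts[otu] = counts
    return out


def sample_metadata(config: ScenarioConfig) -> pd.DataFrame:
    """Per-sample metadata: calendar fields, environment, cell and VLP counts.

    Temperature and nutrients follow annual sinusoids with noise (nutrients
    peaking with the summer rainy season); counts fluctuate lognormally around
    the configured densities.
    """
    rng = config.rng(8)
    months, years = config.calendar()
    t = np.arange(config.n_months)
    phase = 2.0 * np.pi * (months - 8) / 12.0  # warmest around August
    temp = 19.0 + 8.0 * np.cos(phase) + rng.normal(0, 0.8, config.n_months)
    sal = 32.5 - 0.8 * np.cos(phase) + rng.normal(0, 0.3, config.n_months)
    nut_phase = 2.0 * np.pi * (months - 7) / 12.0
    meta = pd.DataFrame(
        {
            "sample_id": [f"M{i:02d}" for i in t],
            "month_index": t,
            "calendar_month": months,
            "year": years,
            "season": [SEASONS[m] for m in months],
            "temp": temp,
            "salinity": sal,
            "NH4": np.exp(0.5 * np.cos(nut_phase)) * rng.lognormal(0, 0.2, config.n_months),
            "NO2": 0.4 * np.exp(0.4 * np.cos(nut_phase)) * rng.lognormal(0, 0.2, config.n_months),
            "NO3": 3.0 * np.exp(0.6 * np.cos(nut_phase)) * rng.lognormal(0, 0.2, config.n_months),
            "PO4": 0.5 * np.exp(0.5 * np.cos(nut_phase)) * rng.lognormal(0, 0.2, config.n_months),
            "SiO2": 6.0 * np.exp(0.5 * np.cos(nut_phase)) * rng.lognormal(0, 0.2, config.n_months),
            "cell_count": config.total_cells_per_ml * rng.lognormal(0, 0.25, config.n_months),
            "vlp_count": config.total_vlp_per_ml * rng.lognormal(0, 0.25, config.n_months),
        }
    ).set_index("sample_id")
    return meta


@dataclass
class SyntheticDataset:
    """Everything one scenario run produces, in memory."""

    config: ScenarioConfig
    truth: PlantedTruth
    host_rel: pd.DataFrame
    viral_rel: pd.DataFrame
    metadata: pd.DataFrame
    amplicon_counts: pd.DataFrame
    virome_counts: pd.DataFrame
    genomes: GenomeSet
    allele_counts: pd.DataFrame
    amplicon_variants: dict[str, list[tuple[str, int]]]


def simulate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Run every generator stage and bundle the results."""
    truth = build_truth(config)
    host_rel = simulate_host_dynamics(config)
    viral_rel = simulate_viral_dynamics(host_rel, truth, config)
    meta = sample_metadata(config)
    depth_rng = config.rng(9)
    depths = depth_rng.integers(*config.amplicon_depth_range, size=config.n_months)
    amplicon_counts = sample_reads(host_rel, depths, config.rng(10))
    virome_counts = sample_reads(viral_rel, config.virome_depth, config.rng(11))
    genomes = generate_genomes(truth, config)
    alleles = generate_site_allele_counts(viral_rel, config)
    variants = generate_amplicon_variants(truth, config)
    return SyntheticDataset(
        config=config,
        truth=truth,
        host_rel=host_rel,
        viral_rel=viral_rel,
        metadata=meta,
        amplicon_counts=amplicon_counts,
        virome_counts=virome_counts,
        genomes=genomes,
        allele_counts=alleles,
        amplicon_variants=variants,
    )
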