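"""Synthetic cosm generator.

Emulates the full experimental substrate: an ancestral genome with paralogous
gene copies, a two-phase evolving population (lab incubation that builds
mid-frequency standing variation, then burial with dormancy adding rare
de novo mutations), 100-isolate pooled sampling, error-bearing pre-aligned
shotgun reads at ~450x depth, and a contaminant community whose composition
drifts by site and time. Truth labels (lineages, planted mutations, pool
compositions, taxon origins) are carried alongside every output so each
downstream stage can be scored without external data.

Reads are emitted pre-aligned and ungapped (known start, match-only CIGAR):
alignment is not part of the method under study. Circular genomes are
supported for bookkeeping but reads never wrap the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig, DetectionRule, SharedCriterion, as_rng

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    if (out == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return out


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Ancestral chromosome used as the coordinate frame for all variants."""

    genome_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self._codes = encode_seq(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return self._codes


@dataclass
class GeneModel:
    """A coding gene span, 0-based half-open, with optional paralog grouping."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    annotation: str = ""
    paralog_group: str | None = None
    selection_class: str = "neutral"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.selection_class not in ("neutral", "selected"):
            raise ValueError(f"bad selection_class {self.selection_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


# variant identity used throughout: (position, ref_base, alt_base)
Mutation = tuple[int, str, str]


@dataclass
class Lineage:
    """A haplotype class: the set of mutations carried by identical isolates,
    plus the fraction of the population it represents."""

    lineage_id: str
    mutation_set: frozenset
    frequency: float

    def __post_init__(self):
        self.mutation_set = frozenset(self.mutation_set)
        if not 0.0 <= self.frequency <= 1.0 + 1e-12:
            raise ValueError(f"lineage frequency {self.frequency} outside [0,1]")


def check_lineages(lineages: list[Lineage], genome_length: int | None = None) -> None:
    total = sum(l.frequency for l in lineages)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"lineage frequencies sum to {total}, expected 1")
    if genome_length is not None:
        for l in lineages:
            for pos, _, _ in l.mutation_set:
                if not 0 <= pos < genome_length:
                    raise ValueError(f"mutation position {pos} outside genome")


@dataclass
class AlignedRead:
    """One pre-aligned, ungapped read with its truth labels."""

    read_id: str
    genome_id: str
    start: int
    sequence: str
    sample_id: str = ""
    true_lineage: str | None = None
    true_taxon: str | None = None


class ReadSet:
    """Array-backed collection of equal-length pre-aligned reads.

    Stores start coordinates, a reads x read_length uint8 base matrix, and a
    per-read truth lineage index. Iteration yields :class:`AlignedRead`
    objects for interoperability with the slow per-read path.
    """

    def __init__(self, genome_id: str, sample_id: str, starts: np.ndarray,
                 seqs: np.ndarray, lineage_names: list[str],
                 lineage_idx: np.ndarray, read_ids: list[str] | None = None):
        self.genome_id = genome_id
        self.sample_id = sample_id
        self.starts = np.asarray(starts, dtype=np.int64)
        self.seqs = np.asarray(seqs, dtype=np.uint8)
        self.lineage_names = list(lineage_names)
        self.lineage_idx = np.asarray(lineage_idx, dtype=np.int32)
        if self.seqs.ndim != 2 or len(self.starts) != self.seqs.shape[0]:
            raise ValueError("starts and sequence matrix are inconsistent")
        self._read_ids = read_ids

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def read_id(self, i: int) -> str:
        if self._read_ids is not None:
            return self._read_ids[i]
        return f"{self.sample_id}:r{i:06d}"

    def true_lineage(self, i: int) -> str:
        return self.lineage_names[self.lineage_idx[i]]

    def __iter__(self):
        for i in range(len(self)):
            yield AlignedRead(
                read_id=self.read_id(i),
                genome_id=self.genome_id,
                start=int(self.starts[i]),
                sequence=decode_seq(self.seqs[i]),
                sample_id=self.sample_id,
                true_lineage=self.true_lineage(i),
            )

    def spanning(self, lo: int, hi: int) -> np.ndarray:
        """Indices of reads covering every position in [lo, hi]."""
        return np.nonzero((self.starts <= lo)
                          & (self.starts + self.read_length > hi))[0]

    def base_at(self, read_indices: np.ndarray, position: int) -> np.ndarray:
        """Base codes of the given reads at an absolute genome position."""
        offs = position - self.starts[read_indices]
        return self.seqs[read_indices, offs]

    @classmethod
    def from_reads(cls, reads: list[AlignedRead]) -> "ReadSet":
        if not reads:
            raise ValueError("empty read list")
        lengths = {len(r.sequence) for r in reads}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires equal-length reads")
        names = sorted({r.true_lineage or "NA" for r in reads})
        name_ix = {n: i for i, n in enumerate(names)}
        seqs = np.stack([encode_seq(r.sequence) for r in reads])
        return cls(
            genome_id=reads[0].genome_id,
            sample_id=reads[0].sample_id,
            starts=np.array([r.start for r in reads]),
            seqs=seqs,
            lineage_names=names,
            lineage_idx=np.array([name_ix[r.true_lineage or "NA"] for r in reads]),
            read_ids=[r.read_id for r in reads],
        )


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

_SELECTED_GENE_IDS = ("znuA_like_1", "znuA_like_2", "folE2_like", "ftsW_like")
_SELECTED_ANNOTATIONS = (
    "High affinity zinc uptake system binding protein, copy 1",
    "High affinity zinc uptake system binding protein, copy 2",
    "GTP cyclohydrolase, zinc-independent folate branch",
    "Putative peptidoglycan transferase",
)
# the gene whose burial-phase fitness tracks the site's zinc level
ZINC_GENE = "folE2_like"
PARALOG_GROUP = "znu-like"


def simulate_ancestor(config: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Draw the ancestral genome and its gene models.

    Genes are non-overlapping, evenly spread, and coding-length divisible by
    three. The first two selected genes form a paralog pair: copy 2 is a
    duplicate of copy 1 diverged at ``paralog_divergence`` of its positions
    (identity >= 80% by construction), which later anchors the read
    best-match misalignment check. Deterministic for a fixed seed.
    """
    config.validate()
    rng = as_rng(rng if rng is not None else config.seed)
    L, n, glen = config.genome_length, config.n_genes, config.gene_length
    if n * glen > L:
        raise ValueError(
            f"genome of {L} bp cannot hold {n} genes of {glen} bp")

    codes = rng.integers(0, 4, size=L, dtype=np.uint8)

    genes: list[GeneModel] = []
    if n > 0:
        slot = L // n
        for i in range(n):
            start = i * slot + (slot - glen) // 2
            end = start + glen
            selected = i < config.n_selected_genes
            if selected and i < len(_SELECTED_GENE_IDS):
                gid, ann = _SELECTED_GENE_IDS[i], _SELECTED_ANNOTATIONS[i]
            else:
                gid, ann = f"gene_{i + 1:05d}", "Hypothetical protein"
            genes.append(GeneModel(
                gene_id=gid, start=start, end=end,
                strand="+" if rng.random() < 0.7 else "-",
                annotation=ann,
                paralog_group=None,
                selection_class="selected" if selected else "neutral",
            ))
        # paralog pair: copy gene 0 over gene 1's span, then diverge
        if n >= 2 and config.n_selected_genes >= 2:
            g1, g2 = genes[0], genes[1]
            g1.paralog_group = g2.paralog_group = PARALOG_GROUP
            g2.strand = g1.strand
            codes[g2.start:g2.end] = codes[g1.start:g1.end]
            n_div = int(round(config.paralog_divergence * glen))
            div_pos = rng.choice(glen, size=n_div, replace=False)
            shift = rng.integers(1, 4, size=n_div).astype(np.uint8)
            codes[g2.start + div_pos] = (codes[g2.start + div_pos] + shift) % 4

    genome = ReferenceGenome(
        genome_id="ancestor", sequence=decode_seq(codes),
        topology=config.topology)
    return genome, genes


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    ca, cb = encode_seq(a), encode_seq(b)
    return float((ca == cb).mean())


# ---------------------------------------------------------------------------
# population dynamics
# ---------------------------------------------------------------------------

def _lineage_fitness(lineage: Lineage, genes: list[GeneModel],
                     base_s: float, gene_selection: dict | None) -> float:
    """Multiplicative fitness: (1+s) per mutation falling in a selected gene.

    ``gene_selection`` optionally overrides s per gene_id (used to couple
    burial-phase selection to site covariates)."""
    w = 1.0
    for pos, _, _ in lineage.mutation_set:
        for g in genes:
            if g.contains(pos):
                if gene_selection is not None and g.gene_id in gene_selection:
                    w *= 1.0 + gene_selection[g.gene_id]
                elif g.selection_class == "selected":
                    w *= 1.0 + base_s
                break
    return w


def _counts_from_frequencies(freqs: np.ndarray, N: int) -> np.ndarray:
    """Largest-remainder apportionment of N individuals to lineages."""
    raw = freqs * N
    counts = np.floor(raw).astype(np.int64)
    short = N - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def evolve_population(genome: ReferenceGenome, genes: list[GeneModel],
                      phase: str, config: SimulationConfig,
                      initial: list[Lineage],
                      rng: np.random.Generator | None = None,
                      generations: int | None = None,
                      gene_selection: dict | None = None) -> list[Lineage]:
    """Wright-Fisher forward simulation of lineage frequencies.

    Each realized generation resamples N individuals multinomially with
    selection weights, then seeds Poisson(mu*N) de novo mutations uniformly
    on the genome, each founding a new lineage at frequency 1/N. The burial
    phase models dormancy by realizing only
    ceil((1 - dormancy_fraction) * generations) generations; the pre phase
    realizes all of them. ``generations`` overrides the configured count
    (e.g. a partial burial up to an intermediate retrieval).
    """
    if phase not in ("pre", "burial"):
        raise ValueError(f"unknown phase {phase!r}")
    check_lineages(initial, len(genome))
    rng = as_rng(rng if rng is not None else config.seed)

    if phase == "pre":
        total_gens = config.generations_pre if generations is None else generations
        realized = total_gens
        N = config.population_size
    else:
        total_gens = config.generations_burial if generations is None else generations
        realized = math.ceil((1.0 - config.dormancy_fraction) * total_gens)
        N = config.burial_population_size

    if realized <= 0:
        return [replace(l) for l in initial]

    lineages = [replace(l) for l in initial]
    fitness = [
        _lineage_fitness(l, genes, config.selection_coefficient, gene_selection)
        for l in lineages
    ]
    counts = _counts_from_frequencies(
        np.array([l.frequency for l in lineages]), N)
    mu = config.mutation_rate
    n_new_total = 0

    for _ in range(realized):
        w = counts * np.asarray(fitness)
        probs = w / w.sum()
        counts = rng.multinomial(N, probs)

        n_new = rng.poisson(mu * N)
        for _ in range(n_new):
            alive = np.nonzero(counts)[0]
            parent = rng.choice(alive, p=counts[alive] / counts[alive].sum())
            pos = int(rng.integers(len(genome)))
            ref = genome.sequence[pos]
            alt = BASES[(_CODE[ref] + int(rng.integers(1, 4))) % 4]
            mut = (pos, ref, alt)
            child = Lineage(
                lineage_id=f"{lineages[parent].lineage_id}+m{n_new_total}",
                mutation_set=lineages[parent].mutation_set | {mut},
                frequency=0.0)
            n_new_total += 1
            counts[parent] -= 1
            lineages.append(child)
            fitness.append(_lineage_fitness(
                child, genes, config.selection_coefficient, gene_selection))
            counts = np.append(counts, 1)

        keep = counts > 0
        if not keep.all():
            lineages = [l for l, k in zip(lineages, keep) if k]
            fitness = [f for f, k in zip(fitness, keep) if k]
            counts = counts[keep]

    out = []
    for l, c in zip(lineages, counts):
        out.append(Lineage(l.lineage_id, l.mutation_set, c / N))
    check_lineages(out, len(genome))
    return out


# ---------------------------------------------------------------------------
# pre-deployment standing variation
# ---------------------------------------------------------------------------

def _plant_gene_mutations(gene: GeneModel, genome: ReferenceGenome,
                          rng: np.random.Generator, read_length: int,
                          n_clustered: int = 3, n_spread: int = 1
                          ) -> list[Mutation]:
    """Plant mutations in one gene: a cluster inside a single read span (the
    substrate for single-read linkage) plus isolated ones elsewhere."""
    window = max(10, min(read_length - 10, gene.length - 1))
    w_start = gene.start + int(rng.integers(0, gene.length - window))
    cluster = rng.choice(window, size=n_clustered, replace=False) + w_start
    rest_pool = np.setdiff1d(np.arange(gene.start, gene.end), cluster)
    spread = rng.choice(rest_pool, size=n_spread, replace=False)
    muts = []
    for pos in sorted(np.concatenate([cluster, spread]).tolist()):
        ref = genome.sequence[pos]
        alt = BASES[(_CODE[ref] + int(rng.integers(1, 4))) % 4]
        muts.append((int(pos), ref, alt))
    return muts


def build_predeployment_population(genome: ReferenceGenome,
                                   genes: list[GeneModel],
                                   config: SimulationConfig,
                                   rng: np.random.Generator | None = None
                                   ) -> tuple[list[Lineage], list[Mutation]]:
    """Construct the carrier-soil standing variation.

    Two mutant haplotype lineages carry clustered mutations concentrated in
    the selected genes (one of them in the second paralog copy), each at a
    frequency drawn inside the 25-50% band; the remainder of the population
    is wild type. The union of the mutant haplotypes is the designated
    pre-deployment ("planted") mutation set that the census stage should
    later recover as shared across aChips.
    """
    rng = as_rng(rng if rng is not None else config.seed)
    by_id = {g.gene_id: g for g in genes}
    sel = [g for g in genes if g.selection_class == "selected"]
    if len(sel) < 3:
        raise ValueError("pre-deployment construction needs >= 3 selected genes")

    zinc = by_id.get(ZINC_GENE, sel[2])
    other = next(g for g in sel if g.gene_id not in (zinc.gene_id, sel[1].gene_id))
    copy2 = sel[1]   # second paralog copy

    l1_muts = (_plant_gene_mutations(zinc, genome, rng, config.read_length) +
               _plant_gene_mutations(other, genome, rng, config.read_length,
                                     n_clustered=2, n_spread=0))
    l2_muts = _plant_gene_mutations(copy2, genome, rng, config.read_length)

    f1 = float(rng.uniform(0.28, 0.42))
    f2 = float(rng.uniform(0.26, 0.40))
    lineages = [
        Lineage("wt", frozenset(), 1.0 - f1 - f2),
        Lineage("pre_L1", frozenset(l1_muts), f1),
        Lineage("pre_L2", frozenset(l2_muts), f2),
    ]
    check_lineages(lineages, len(genome))
    return lineages, sorted(set(l1_muts) | set(l2_muts))


# ---------------------------------------------------------------------------
# pooled sampling and reads
# ---------------------------------------------------------------------------

def sample_isolate_pool(lineages: list[Lineage], pool_size: int,
                        rng: np.random.Generator | int | None = None) -> dict:
    """Multinomial draw of ``pool_size`` isolates by lineage frequency.

    Returns {lineage_id: isolate count}; counts sum to pool_size, so any
    carried mutation's pool-level frequency is a multiple of 1/pool_size.
    """
    if not lineages:
        raise ValueError("cannot sample a pool from an empty lineage list")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    check_lineages(lineages)
    rng = as_rng(rng)
    freqs = np.array([l.frequency for l in lineages])
    counts = rng.multinomial(pool_size, freqs / freqs.sum())
    return {l.lineage_id: int(c) for l, c in zip(lineages, counts)}


def pool_mutation_frequencies(lineages: list[Lineage], pool: dict) -> dict:
    """Truth pool frequency of every mutation carried by >= 1 pooled isolate."""
    total = sum(pool.values())
    freq: dict[Mutation, float] = {}
    for l in lineages:
        c = pool.get(l.lineage_id, 0)
        if c == 0:
            continue
        for m in l.mutation_set:
            freq[m] = freq.get(m, 0.0) + c / total
    return freq


def generate_reads(pool: dict, lineages: list[Lineage],
                   genome: ReferenceGenome, config: SimulationConfig,
                   rng: np.random.Generator | int | None = None,
                   sample_id: str = "sample") -> ReadSet:
    """Shotgun-sequence an isolate pool into pre-aligned reads.

    Read count is round(mean_depth * genome_length / read_length); starts are
    uniform over the linear span (wrapping reads are not emitted); each read
    is drawn from a lineage proportional to its pool count, carries that
    lineage's mutations within its span, and then per-base substitution
    errors at ``error_rate``. Error sites are drawn as a Binomial number of
    distinct base positions; the vanishing collision deficit (< n_err/2N of
    the rate) is ignored.
    """
    rng = as_rng(rng)
    L, rl = len(genome), config.read_length
    if rl > L:
        raise ValueError("read_length exceeds genome length")
    ids = [l.lineage_id for l in lineages if pool.get(l.lineage_id, 0) > 0]
    lins = [l for l in lineages if pool.get(l.lineage_id, 0) > 0]
    weights = np.array([pool[i] for i in ids], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("pool holds no isolates")

    n_reads = int(round(config.mean_depth * L / rl))
    lineage_idx = rng.choice(len(ids), size=n_reads, p=weights / weights.sum())
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    offsets = np.arange(rl)
    seqs = genome.codes[starts[:, None] + offsets]

    for li, lin in enumerate(lins):
        if not lin.mutation_set:
            continue
        rows = np.nonzero(lineage_idx == li)[0]
        if rows.size == 0:
            continue
        rstarts = starts[rows]
        for pos, _, alt in lin.mutation_set:
            hit = (rstarts <= pos) & (rstarts + rl > pos)
            if hit.any():
                rr = rows[hit]
                seqs[rr, pos - starts[rr]] = _CODE[alt]

    total = n_reads * rl
    n_err = rng.binomial(total, config.error_rate)
    if n_err:
        flat = np.unique(rng.integers(0, total, size=n_err))
        r, c = np.divmod(flat, rl)
        shift = rng.integers(1, 4, size=flat.size).astype(np.uint8)
        seqs[r, c] = (seqs[r, c] + shift) % 4

    return ReadSet(genome_id=genome.genome_id, sample_id=sample_id,
                   starts=starts, seqs=seqs, lineage_names=ids,
                   lineage_idx=lineage_idx)


# ---------------------------------------------------------------------------
# contaminant community
# ---------------------------------------------------------------------------

def simulate_contaminants(config: SimulationConfig,
                          rng: np.random.Generator | int | None = None,
                          site_sigma: float | None = None):
    """Simulate the non-focal taxon community inside the aChips.

    Baseline taxon abundances are log-normal with strong dominance; over
    time the baseline spread relaxes (rare survivors of autoclaving grow,
    raising alpha diversity) while site-specific log-normal perturbations
    grow (separating sites in ordination). The focal species' read share
    declines on the logit scale. A configurable fraction of taxa is flagged
    absent from the pre-deployment pool (default 0, emulating the
    observation that >98% of non-focal reads trace back to the carrier
    soil). Returns (CommunityTable, focal-fraction Series, taxon-truth
    DataFrame).
    """
    from .community import CommunityTable

    rng = as_rng(rng if rng is not None else config.seed)
    s_sigma = config.site_sigma if site_sigma is None else site_sigma
    sites = [f"S{i+1}" for i in range(config.n_sites)]
    times = [t for t in (3, 10) if t in config.timepoints] or [config.timepoints[0]]
    n_tax = config.n_taxa
    focal = "focal_sp"
    taxa = [focal] + [f"taxon_{i+1:03d}" for i in range(n_tax)]

    base = rng.normal(0.0, config.community_sigma0, size=n_tax)
    site_load = rng.normal(0.0, 1.0, size=(len(sites), n_tax))

    n_ext = int(round(config.external_taxon_fraction * n_tax))
    ext_idx = rng.choice(n_tax, size=n_ext, replace=False) if n_ext else np.array([], int)
    ext_site = {int(i): sites[int(rng.integers(len(sites)))] for i in ext_idx}
    origin = np.array(["pre_deployment"] * n_tax, dtype=object)
    origin[ext_idx] = "external"

    def sample_counts(tau: float, site_i: int | None, focal_share: float,
                      achip_noise: bool, exact: bool = False) -> np.ndarray:
        logab = base * (1.0 - config.evenness_gain * tau)
        if site_i is not None:
            logab = logab + s_sigma * tau * site_load[site_i]
        if achip_noise:
            logab = logab + rng.normal(0.0, config.achip_sigma, size=n_tax)
        w = np.exp(logab)
        present = np.ones(n_tax, bool)
        for i, s in ext_site.items():
            present[i] = site_i is not None and sites[site_i] == s
        w = w * present
        p = np.empty(n_tax + 1)
        p[0] = focal_share
        p[1:] = (1.0 - focal_share) * w / w.sum()
        if exact:
            # the pre-deployment carrier soil is characterized exhaustively:
            # expected counts, floored at one read per present taxon, so
            # presence/absence truth is exact for source attribution
            counts = np.round(p * config.community_reads).astype(np.int64)
            counts[1:][present & (counts[1:] == 0)] = 1
            return counts
        return rng.multinomial(config.community_reads, p)

    logit0 = math.log(config.focal_share0 / (1.0 - config.focal_share0))

    cols, meta_rows = {}, []
    pre_share = config.focal_share0
    cols["pre_deployment"] = sample_counts(0.0, None, pre_share, False,
                                           exact=True)
    meta_rows.append(("pre_deployment", "pre", 0, "pre"))
    n_achips_comm = max(2, config.n_achips_per_site // len(config.timepoints))
    for t in times:
        share = 1.0 / (1.0 + math.exp(-(logit0 - config.focal_decline * t)))
        tau = t / 10.0
        for si, site in enumerate(sites):
            for a in range(n_achips_comm):
                sid = f"{site}-c{a+1:02d}-t{t}"
                cols[sid] = sample_counts(tau, si, share, True)
                meta_rows.append((sid, site, t, f"{site}-c{a+1:02d}"))

    counts = pd.DataFrame(cols, index=taxa)
    meta = pd.DataFrame(meta_rows,
                        columns=["sample_id", "site", "timepoint", "achip_id"]
                        ).set_index("sample_id")
    table = CommunityTable(counts=counts, meta=meta, focal_taxon=focal)
    focal_frac = 100.0 * counts.loc[focal] / counts.sum(axis=0)
    truth = pd.DataFrame({"taxon": taxa[1:], "origin": origin,
                          "exclusive_site": [ext_site.get(i, "")
                                             for i in range(n_tax)]})
    return table, focal_frac, truth


# ---------------------------------------------------------------------------
# the default synthetic experiment
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    sample_id: str
    achip_id: str
    site: str
    timepoint: int
    lineages: list
    pool: dict
    pool_freq: dict          # truth pool frequency per mutation


@dataclass
class ExperimentTruth:
    planted: list            # designated pre-deployment mutation set
    predeployment_lineages: list
    covariates: pd.DataFrame  # per-site abiotic covariates
    zinc_gene: str


@dataclass
class ExperimentResult:
    config: SimulationConfig
    genome: ReferenceGenome
    genes: list
    samples: list            # list[SyntheticSample]
    calls_by_sample: dict    # sample_id -> list[VariantCall], annotated
    truth: ExperimentTruth
    reads_by_sample: dict = field(default_factory=dict)

    @property
    def metas(self):
        from .census import SampleMeta
        return [SampleMeta(sample_id=s.sample_id, achip_id=s.achip_id,
                           site=s.site, timepoint=s.timepoint,
                           species="focal_sp", pool_size=self.config.pool_size)
                for s in self.samples]


def _site_covariates(sites: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Abiotic covariates spanning the ranges reported for the burial farms."""
    return pd.DataFrame({
        "zinc_ppm": rng.uniform(0.8, 3.2, size=len(sites)).round(2),
        "pH": rng.uniform(5.6, 7.1, size=len(sites)).round(2),
        "organic_matter_pct": rng.uniform(2.2, 4.9, size=len(sites)).round(2),
    }, index=pd.Index(sites, name="site"))


def simulate_experiment(config: SimulationConfig | None = None,
                        seed: int | None = None,
                        keep_reads: bool = False) -> ExperimentResult:
    """Run the default synthetic experiment end to end (in memory).

    Layout: n_sites x n_achips_per_site aChips, each assigned one retrieval
    timepoint (balanced across 3/10/24 months). Every aChip starts from the
    same constructed pre-deployment population, evolves through its own
    dormancy-thinned burial phase (with the zinc-responsive gene's fitness
    coupled to the site's zinc level), is pooled to 100 isolates, sequenced
    at ~450x, piled up, and variant-called with the default detection rule.
    """
    from .pileup import build_pileup, call_variants, annotate_all

    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = as_rng(config.seed)

    genome, genes = simulate_ancestor(config, rng)
    pre_lineages, planted = build_predeployment_population(
        genome, genes, config, rng)

    sites = [f"S{i+1}" for i in range(config.n_sites)]
    covars = _site_covariates(sites, rng)
    zinc = covars["zinc_ppm"]
    zscore = (zinc - zinc.mean()) / (zinc.std(ddof=0) or 1.0)

    rule = DetectionRule()
    max_t = max(config.timepoints)
    samples, calls_by_sample, reads_by_sample = [], {}, {}
    for site in sites:
        gene_sel = {g.gene_id: 0.0 for g in genes if g.selection_class == "selected"}
        gene_sel[ZINC_GENE] = -config.abiotic_beta * float(zscore[site])
        for a in range(config.n_achips_per_site):
            t = config.timepoints[a % len(config.timepoints)]
            achip = f"{site}-a{a+1:02d}"
            sid = f"{achip}-t{t}"
            gens = int(round(config.generations_burial * t / max_t))
            lineages = evolve_population(
                genome, genes, "burial", config, pre_lineages,
                rng=rng, generations=gens, gene_selection=gene_sel)
            pool = sample_isolate_pool(lineages, config.pool_size, rng)
            reads = generate_reads(pool, lineages, genome, config, rng,
                                   sample_id=sid)
            pu = build_pileup(reads, genome)
            calls = annotate_all(call_variants(pu, genome, rule), genes, genome)
            samples.append(SyntheticSample(
                sample_id=sid, achip_id=achip, site=site, timepoint=t,
                lineages=lineages, pool=pool,
                pool_freq=pool_mutation_frequencies(lineages, pool)))
            calls_by_sample[sid] = calls
            if keep_reads:
                reads_by_sample[sid] = reads

    truth = ExperimentTruth(planted=planted,
                            predeployment_lineages=pre_lineages,
                            covariates=covars, zinc_gene=ZINC_GENE)
    return ExperimentResult(config=config, genome=genome, genes=genes,
                            samples=samples, calls_by_sample=calls_by_sample,
                            truth=truth, reads_by_sample=reads_by_sample)


def simulate_null_frequencies(n_variants: int, sites: list[str],
                              reps_per_site: int, depth: int = 450,
                              pool_size: int = 100,
                              rng: np.random.Generator | int | None = None
                              ) -> pd.DataFrame:
    """Null simulator for statistical calibration: pooled-then-sequenced
    frequencies with no site effect whatsoever.

    Each variant has one true population frequency (uniform in 0.2-0.5);
    every sample passes it through 100-isolate pooling and then binomial
    read sampling at ``depth``. Long-format DataFrame: variant, site,
    sample, frequency.
    """
    rng = as_rng(rng)
    p = rng.uniform(0.2, 0.5, size=n_variants)
    rows = []
    for v in range(n_variants):
        for site in sites:
            for r in range(reps_per_site):
                pooled = rng.binomial(pool_size, p[v]) / pool_size
                f = rng.binomial(depth, pooled) / depth
                rows.append((f"v{v}", site, f"{site}-r{r}", f))
    return pd.DataFrame(rows, columns=["variant", "site", "sample", "frequency"])
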