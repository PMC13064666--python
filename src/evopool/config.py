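"""Run-level configuration objects shared across the pipeline.

All rates are per-base or per-genome probabilities in [0, 1]; coordinates are
0-based half-open internally and converted to 1-based only at file boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import yaml


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cosm experiment.

    The defaults encode the study conditions being emulated: five burial
    sites, twelve 100-isolate pools per site split over the 3/10/24-month
    retrievals, ~450x read depth, and a pre-deployment population whose
    selected-gene haplotypes sit in the 25-50% frequency band.
    """

    seed: int = 0

    # ancestral genome
    genome_length: int = 20_000
    n_genes: int = 20
    gene_length: int = 600          # divisible by 3
    n_selected_genes: int = 4
    paralog_divergence: float = 0.10
    topology: str = "linear"

    # population dynamics
    population_size: int = 10_000       # pre-deployment (carrier soil) N
    burial_population_size: int = 1_000  # effective N inside one buried aChip
    mutation_rate: float = 0.003        # mutations / genome / generation
    generations_pre: int = 100
    generations_burial: int = 60        # full 24-month burial, before dormancy
    dormancy_fraction: float = 0.8      # fraction of burial generations skipped
    selection_coefficient: float = 0.1  # per mutation in a selected gene (pre phase)

    # pooled sampling and sequencing
    pool_size: int = 100
    mean_depth: float = 450.0
    read_length: int = 150
    error_rate: float = 0.001

    # experiment layout
    n_sites: int = 5
    n_achips_per_site: int = 12
    timepoints: tuple = (3, 10, 24)

    # abiotic covariate coupling: burial-phase selection on the zinc-responsive
    # gene scales with the site's standardized zinc level (negative association)
    abiotic_beta: float = 0.02

    # contaminant community
    n_taxa: int = 40
    community_reads: int = 50_000
    community_sigma0: float = 2.0     # baseline log-abundance spread (dominance)
    evenness_gain: float = 0.6        # how fast rare taxa wake up over time
    site_sigma: float = 1.2           # site-specific drift magnitude at t=10
    achip_sigma: float = 0.3
    focal_share0: float = 0.6         # focal read share in pre-deployment soil
    focal_decline: float = 0.12       # per-month decline on the logit scale
    external_taxon_fraction: float = 0.0  # taxa absent from pre-deployment soil

    def validate(self) -> None:
        for name in ("mutation_rate", "dormancy_fraction", "error_rate",
                     "paralog_divergence", "external_taxon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.population_size < self.pool_size:
            raise ValueError("population_size must be >= pool_size")
        if self.burial_population_size < self.pool_size:
            raise ValueError("burial_population_size must be >= pool_size")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome length")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "timepoints" in kwargs:
            kwargs["timepoints"] = tuple(kwargs["timepoints"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class DetectionRule:
    """Pool-aware variant detection thresholds.

    ``min_frequency`` defaults to 0.01 -- the smallest positive frequency a
    single isolate can contribute to a 100-isolate pool, i.e. the design's
    detection floor for rare variants. ``min_alt_reads`` suppresses singleton
    sequencing errors at ~450x depth.
    """

    min_frequency: float = 0.01
    min_alt_reads: int = 2

    def __post_init__(self):
        if self.min_frequency < 0 or self.min_alt_reads < 0:
            raise ValueError("detection thresholds must be >= 0")


def detection_floor(pool_size: int) -> float:
    """Smallest positive variant frequency representable in an isolate pool.

    One carrier isolate out of ``pool_size`` contributes 1/pool_size; rarer
    population variants are either absent from the pool or indistinguishable
    from this floor.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return 1.0 / pool_size


@dataclass(frozen=True)
class SharedCriterion:
    """k-of-n prevalence rule: a variant is 'shared' if detected in >= k of
    the n sampled pools (e.g. 54 of 59, or 13 of 14)."""

    k: int
    n: int

    def __post_init__(self):
        if not 0 < self.k <= self.n:
            raise ValueError(f"need 0 < k <= n, got k={self.k}, n={self.n}")

    @classmethod
    def scaled(cls, n: int, k_ref: int = 54, n_ref: int = 59) -> "SharedCriterion":
        """Scale a reference k-of-n rule to a layout with ``n`` samples."""
        return cls(k=min(n, math.ceil(n * k_ref / n_ref)), n=n)
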