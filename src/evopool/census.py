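"""Cross-sample mutation bookkeeping.

Builds the variant x sample frequency/detection matrix, applies the k-of-n
shared-mutation prevalence rule, computes once-per-site Venn partitions,
site-unique-gene parallelism scans, per-gene N:S summaries, and per-aChip
shared/non-shared counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import chain, combinations

import numpy as np
import pandas as pd

from .config import DetectionRule, SharedCriterion
from .pileup import VariantCall


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced 100-isolate pool."""

    sample_id: str
    achip_id: str
    site: str
    timepoint: int
    species: str = ""
    pool_size: int = 100

    def __post_init__(self):
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")


@dataclass
class MutationMatrix:
    """Variant x sample census: frequencies, detection flags, annotations."""

    frequencies: pd.DataFrame    # index: (position, ref, alt); columns: sample_id
    detected: pd.DataFrame       # same shape, bool
    variant_info: pd.DataFrame   # index as above; gene_id, effect
    samples: pd.DataFrame        # index sample_id; achip_id, site, timepoint, ...
    rule: DetectionRule

    def __post_init__(self):
        if not self.frequencies.index.equals(self.detected.index):
            raise ValueError("frequency/detected index mismatch")
        if list(self.frequencies.columns) != list(self.detected.columns):
            raise ValueError("frequency/detected column mismatch")
        bad = self.detected.to_numpy() & (
            self.frequencies.to_numpy() < self.rule.min_frequency)
        if bad.any():
            raise ValueError("detected cell below the rule's min_frequency")

    @property
    def n_samples(self) -> int:
        return self.frequencies.shape[1]

    def subset_samples(self, sample_ids) -> "MutationMatrix":
        return MutationMatrix(self.frequencies[sample_ids],
                              self.detected[sample_ids],
                              self.variant_info, self.samples.loc[sample_ids],
                              self.rule)


def build_matrix(calls_by_sample: dict, metas: list[SampleMeta],
                 rule: DetectionRule | None = None) -> MutationMatrix:
    """Merge per-sample call lists into one census matrix.

    The variant universe is the union of call keys; undetected cells hold
    frequency 0. Effect annotation is preserved from the first annotated
    call of each variant.
    """
    rule = rule or DetectionRule()
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    if set(ids) != set(calls_by_sample):
        raise ValueError("metadata and call dictionary disagree on samples")

    info: dict[tuple, dict] = {}
    for sid in ids:
        for c in calls_by_sample[sid]:
            if c.key not in info:
                info[c.key] = {"gene_id": c.gene_id, "effect": c.effect}

    keys = sorted(info)
    index = pd.MultiIndex.from_tuples(keys, names=["position", "ref", "alt"])
    freq = pd.DataFrame(0.0, index=index, columns=ids)
    det = pd.DataFrame(False, index=index, columns=ids)
    for sid in ids:
        for c in calls_by_sample[sid]:
            freq.loc[c.key, sid] = c.frequency
            det.loc[c.key, sid] = (c.alt_count >= rule.min_alt_reads
                                   and c.frequency >= rule.min_frequency)

    vinfo = pd.DataFrame([info[k] for k in keys], index=index)
    samples = pd.DataFrame(
        [{"achip_id": m.achip_id, "site": m.site, "timepoint": m.timepoint,
          "species": m.species, "pool_size": m.pool_size} for m in metas],
        index=pd.Index(ids, name="sample_id"))
    return MutationMatrix(freq, det, vinfo, samples, rule)


@dataclass
class SharedMutationSet:
    """Exhaustive, exclusive partition of the variant universe under a
    k-of-n prevalence rule."""

    criterion: SharedCriterion
    shared: list
    non_shared: list

    def is_shared(self, key) -> bool:
        return key in self._shared_set

    def __post_init__(self):
        self._shared_set = set(self.shared)


def classify_shared(matrix: MutationMatrix,
                    criterion: SharedCriterion) -> SharedMutationSet:
    """Shared iff detected in >= k of the matrix's n samples."""
    if criterion.n != matrix.n_samples:
        raise ValueError(
            f"criterion n={criterion.n} does not match the "
            f"{matrix.n_samples} samples in the matrix")
    prevalence = matrix.detected.sum(axis=1)
    shared = prevalence[prevalence >= criterion.k].index.tolist()
    non_shared = prevalence[prevalence < criterion.k].index.tolist()
    return SharedMutationSet(criterion=criterion, shared=shared,
                             non_shared=non_shared)


def venn_partition(matrix: MutationMatrix, timepoint: int | None = None
                   ) -> dict:
    """Counts of distinct variants per nonempty site subset.

    A variant counts once for a site if detected in >= 1 of that site's
    aChips (at the given timepoint, if any); each variant then lands in
    exactly one region -- the subset of sites where it is present.
    Returns {frozenset(sites): count} over all 2^m - 1 nonempty subsets.
    """
    samples = matrix.samples
    if timepoint is not None:
        samples = samples[samples["timepoint"] == timepoint]
    sites = sorted(samples["site"].unique())
    if not sites:
        raise ValueError("no sites at the requested timepoint")

    present = {}
    for site in sites:
        cols = samples.index[samples["site"] == site]
        present[site] = matrix.detected[cols].any(axis=1)

    regions = {frozenset(sub): 0
               for r in range(1, len(sites) + 1)
               for sub in combinations(sites, r)}
    member = pd.DataFrame(present)          # variants x sites, bool
    for _, row in member.iterrows():
        sub = frozenset(s for s in sites if row[s])
        if sub:
            regions[sub] += 1
    return regions


def site_unique_genes(matrix: MutationMatrix,
                      majority_fraction: float = 0.5) -> dict:
    """Per-site lists of genes mutated in most of that site's aChips and in
    none of any other site's -- the within-site parallelism signature.

    A gene counts as mutated in an aChip if the aChip has >= 1 detected
    non-synonymous variant in it.
    """
    sites = sorted(matrix.samples["site"].unique())
    if len(sites) < 2:
        raise ValueError("site-unique scan needs >= 2 sites")
    nonsyn = matrix.variant_info["effect"] == "non-synonymous"
    det = matrix.detected.loc[nonsyn]
    gene_of = matrix.variant_info.loc[nonsyn, "gene_id"]

    # gene x achip: any detected non-synonymous variant
    achip_of = matrix.samples["achip_id"]
    site_of_achip = matrix.samples.groupby("achip_id")["site"].first()
    gene_achip = (det.T.groupby(achip_of).any().T
                  .groupby(gene_of.rename("gene_id")).any())

    out: dict[str, list] = {s: [] for s in sites}
    for gene, row in gene_achip.iterrows():
        if gene is None:
            continue
        hit_sites = {}
        for site in sites:
            achips = site_of_achip.index[site_of_achip == site]
            hits = int(row[achips].sum())
            hit_sites[site] = (hits, len(achips))
        mutated_sites = [s for s, (h, _) in hit_sites.items() if h > 0]
        if len(mutated_sites) == 1:
            s = mutated_sites[0]
            h, total = hit_sites[s]
            if h > majority_fraction * total:
                out[s].append(gene)
    return {s: sorted(g) for s, g in out.items()}


# ---------------------------------------------------------------------------
# N:S summaries
# ---------------------------------------------------------------------------

def ns_ratio_from_means(mean_nonsyn: float, mean_syn: float) -> float | None:
    """Ratio of mean non-synonymous to mean synonymous counts, rounded
    half-up to 2 decimals; None (NA) when the synonymous mean is zero."""
    if mean_syn == 0:
        return None
    ratio = Decimal(str(mean_nonsyn)) / Decimal(str(mean_syn))
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class GeneMutationSummary:
    gene_id: str
    n_achips: int
    mean_nonsyn: float
    se_nonsyn: float
    mean_syn: float
    se_syn: float
    ns_ratio: float | None


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se


def gene_mutation_summary(matrix: MutationMatrix) -> list[GeneMutationSummary]:
    """Per-gene mean +/- SE mutation counts over the aChips that possessed
    mutations (of either effect class) in that gene, and their N:S ratio."""
    info = matrix.variant_info
    coding = info["gene_id"].notna() & info["effect"].isin(
        ["synonymous", "non-synonymous"])
    det = matrix.detected.loc[coding]
    gene_of = info.loc[coding, "gene_id"]
    effect_of = info.loc[coding, "effect"]
    achip_of = matrix.samples["achip_id"]

    summaries = []
    for gene in sorted(gene_of.unique()):
        in_gene = gene_of == gene
        per_achip = det.loc[in_gene].T.groupby(achip_of).sum().T  # variant x achip
        ns_counts = per_achip.loc[effect_of[in_gene] == "non-synonymous"].sum(axis=0)
        syn_counts = per_achip.loc[effect_of[in_gene] == "synonymous"].sum(axis=0)
        qualifying = (ns_counts + syn_counts) > 0
        if not qualifying.any():
            continue
        ns_vals = ns_counts[qualifying].to_numpy(float)
        syn_vals = syn_counts[qualifying].to_numpy(float)
        mean_ns, se_ns = _mean_se(ns_vals)
        mean_syn, se_syn = _mean_se(syn_vals)
        summaries.append(GeneMutationSummary(
            gene_id=gene, n_achips=int(qualifying.sum()),
            mean_nonsyn=mean_ns, se_nonsyn=se_ns,
            mean_syn=mean_syn, se_syn=se_syn,
            ns_ratio=ns_ratio_from_means(mean_ns, mean_syn)))
    return summaries


def per_achip_counts(matrix: MutationMatrix,
                     shared: SharedMutationSet) -> pd.DataFrame:
    """Per-sample counts of detected non-synonymous mutations, partitioned
    into shared vs non-shared; index sample_id, with site/timepoint."""
    nonsyn = matrix.variant_info["effect"] == "non-synonymous"
    det = matrix.detected.loc[nonsyn]
    is_shared = det.index.to_series().apply(lambda k: shared.is_shared(k))
    n_shared = det.loc[is_shared].sum(axis=0)
    n_non = det.loc[~is_shared].sum(axis=0)
    out = pd.DataFrame({"n_shared": n_shared.astype(int),
                        "n_non_shared": n_non.astype(int)})
    out = out.join(matrix.samples[["achip_id", "site", "timepoint"]])
    return out


def site_time_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE shared and non-shared counts per site x timepoint."""
    def agg(g):
        res = {}
        for col in ("n_shared", "n_non_shared"):
            m, se = _mean_se(g[col].to_numpy(float))
            res[f"{col}_mean"], res[f"{col}_se"] = m, se
        res["n_achips"] = len(g)
        return pd.Series(res)
    return (counts.groupby(["site", "timepoint"])
            .apply(agg, include_groups=False).reset_index())
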