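"""Mutation census: matrix assembly, k-of-n shared classification, Venn
partitions, site-unique parallelism, N:S summaries and per-aChip counts,
each validated against brute-force recounts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from evopool.config import DetectionRule, SharedCriterion
from evopool.census import (SampleMeta, build_matrix, classify_shared,
                            gene_mutation_summary, ns_ratio_from_means,
                            per_achip_counts, site_unique_genes,
                            venn_partition)
from evopool.pileup import VariantCall


def _call(pos, alt="A", freq=0.3, depth=100, gene=None, effect=None,
          ref="C"):
    return VariantCall(position=pos, ref_base=ref, alt_base=alt,
                       alt_count=int(round(freq * depth)), depth=depth,
                       frequency=freq, gene_id=gene, effect=effect)


def _meta(sid, site="S1", achip=None, t=3):
    return SampleMeta(sample_id=sid, achip_id=achip or sid, site=site,
                      timepoint=t, species="sp", pool_size=100)


def _random_matrix(rng, n_var=20, sites=("S1", "S2", "S3"), per_site=4,
                   p_detect=0.3):
    metas, calls = [], {}
    variants = [(37 * i + 5, "C", "A") for i in range(n_var)]
    genes = [f"g{i % 5}" for i in range(n_var)]
    effects = ["non-synonymous" if i % 3 else "synonymous"
               for i in range(n_var)]
    for site in sites:
        for a in range(per_site):
            sid = f"{site}-a{a}"
            metas.append(_meta(sid, site=site))
            cs = []
            for v, g, e in zip(variants, genes, effects):
                if rng.random() < p_detect:
                    cs.append(_call(v[0], alt=v[2], freq=float(
                        rng.uniform(0.02, 0.5)), gene=g, effect=e))
            calls[sid] = cs
    return build_matrix(calls, metas, DetectionRule()), metas, calls


class TestBuildMatrix:
    def test_single_sample_shape(self):
        calls = {"s1": [_call(1), _call(5), _call(9)]}
        m = build_matrix(calls, [_meta("s1")])
        assert m.frequencies.shape == (3, 1)
        assert (m.detected.to_numpy()).all()

    def test_disjoint_samples_have_zero_cells(self):
        calls = {"s1": [_call(1), _call(5)], "s2": [_call(9), _call(12)]}
        m = build_matrix(calls, [_meta("s1"), _meta("s2")])
        assert m.frequencies.shape == (4, 2)
        assert (m.frequencies.to_numpy() == 0).sum() == 4

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix({"s1": []}, [_meta("s1"), _meta("s1")])

    def test_matches_brute_force_dictionary_merge(self, rng):
        m, metas, calls = _random_matrix(rng)
        merged = {}
        for sid, cs in calls.items():
            for c in cs:
                merged.setdefault(c.key, {})[sid] = c.frequency
        assert set(m.frequencies.index) == set(merged)
        for key, by_sample in merged.items():
            for meta in metas:
                want = by_sample.get(meta.sample_id, 0.0)
                assert m.frequencies.loc[key, meta.sample_id] == want


class TestClassifyShared:
    def _matrix_with_prevalence(self, n_samples, prevalences):
        metas = [_meta(f"s{i}") for i in range(n_samples)]
        calls = {m.sample_id: [] for m in metas}
        for v, prev in enumerate(prevalences):
            for i in range(prev):
                calls[f"s{i}"].append(_call(10 * v + 1, freq=0.3))
        return build_matrix(calls, metas)

    def test_54_of_59_rule(self):
        # variants seen in 54 and 53 of 59 pools under the k=54 rule
        m = self._matrix_with_prevalence(59, [54, 53])
        res = classify_shared(m, SharedCriterion(54, 59))
        assert [k[0] for k in res.shared] == [1]
        assert [k[0] for k in res.non_shared] == [11]

    def test_never_detected_variant_is_non_shared(self):
        metas = [_meta(f"s{i}") for i in range(3)]
        calls = {m.sample_id: [] for m in metas}
        calls["s0"] = [_call(1, freq=0.005, depth=1000)]  # below the floor
        m = build_matrix(calls, metas)
        res = classify_shared(m, SharedCriterion(1, 3))
        assert res.shared == [] and len(res.non_shared) == 1

    def test_k_equals_one_boundary(self, rng):
        m, _, _ = _random_matrix(rng, n_var=10)
        res = classify_shared(m, SharedCriterion(1, m.n_samples))
        detected_anywhere = m.detected.any(axis=1)
        assert set(res.shared) == set(detected_anywhere[detected_anywhere].index)

    def test_monotone_in_k(self, rng):
        m, _, _ = _random_matrix(rng)
        prev = None
        for k in range(1, m.n_samples + 1):
            cur = set(classify_shared(m, SharedCriterion(k, m.n_samples)).shared)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_criterion_must_match_sample_count(self, rng):
        m, _, _ = _random_matrix(rng)
        with pytest.raises(ValueError, match="does not match"):
            classify_shared(m, SharedCriterion(2, m.n_samples + 1))


class TestVennPartition:
    def test_two_site_example(self):
        # site1 holds {A,B}, site2 holds {B,C} -> regions 1/1/1
        metas = [_meta("x", site="S1"), _meta("y", site="S2")]
        calls = {"x": [_call(1), _call(11)], "y": [_call(11), _call(21)]}
        m = build_matrix(calls, metas)
        regions = venn_partition(m)
        assert regions[frozenset({"S1"})] == 1
        assert regions[frozenset({"S2"})] == 1
        assert regions[frozenset({"S1", "S2"})] == 1

    def test_multiple_achips_count_once_per_site(self):
        metas = [_meta(f"s{i}", site="S1") for i in range(3)] + \
            [_meta("t", site="S2")]
        calls = {m.sample_id: [_call(1)] for m in metas[:3]}
        calls["t"] = []
        m = build_matrix(calls, metas)
        regions = venn_partition(m)
        assert regions[frozenset({"S1"})] == 1

    def test_matches_power_set_enumeration(self, rng):
        m, metas, _ = _random_matrix(rng)
        regions = venn_partition(m, timepoint=3)
        sites = sorted({meta.site for meta in metas})
        # oracle: per-variant site membership, then exact-region count
        oracle = {frozenset(sub): 0
                  for r in range(1, len(sites) + 1)
                  for sub in itertools.combinations(sites, r)}
        for key in m.detected.index:
            sub = frozenset(
                s for s in sites
                if m.detected.loc[key, [meta.sample_id for meta in metas
                                        if meta.site == s]].any())
            if sub:
                oracle[sub] += 1
        assert regions == oracle
        assert sum(regions.values()) == int(m.detected.any(axis=1).sum())

    def test_invariant_to_sample_order(self, rng):
        m, metas, calls = _random_matrix(rng)
        shuffled = list(reversed(metas))
        m2 = build_matrix(calls, shuffled)
        assert venn_partition(m) == venn_partition(m2)


class TestSiteUniqueGenes:
    def _matrix(self, hits):
        # hits: {(site, achip_index): [gene,...]} over 2 sites x 4 achips
        metas, calls = [], {}
        pos_of = {}
        for site in ("S1", "S2"):
            for a in range(4):
                sid = f"{site}-a{a}"
                metas.append(_meta(sid, site=site))
                cs = []
                for gene in hits.get((site, a), []):
                    pos = pos_of.setdefault(gene, 100 * len(pos_of) + 1)
                    cs.append(_call(pos, gene=gene, effect="non-synonymous"))
                calls[sid] = cs
        return build_matrix(calls, metas)

    def test_majority_and_exclusivity(self):
        m = self._matrix({("S1", 0): ["gA"], ("S1", 1): ["gA"],
                          ("S1", 2): ["gA"]})
        assert site_unique_genes(m) == {"S1": ["gA"], "S2": []}

    def test_single_foreign_achip_disqualifies(self):
        m = self._matrix({("S1", 0): ["gA"], ("S1", 1): ["gA"],
                          ("S1", 2): ["gA"], ("S2", 0): ["gA"]})
        assert site_unique_genes(m) == {"S1": [], "S2": []}

    def test_matches_exhaustive_scan(self, rng):
        m, metas, calls = _random_matrix(rng, n_var=15, per_site=4)
        got = site_unique_genes(m, majority_fraction=0.5)
        # oracle: plain-dict recount over calls
        sites = sorted({meta.site for meta in metas})
        achips_of = {s: [meta.achip_id for meta in metas if meta.site == s]
                     for s in sites}
        gene_hits = {}
        for meta in metas:
            for c in calls[meta.sample_id]:
                if c.effect == "non-synonymous" and c.frequency >= 0.01:
                    gene_hits.setdefault(c.gene_id, set()).add(
                        (meta.site, meta.achip_id))
        oracle = {s: [] for s in sites}
        for gene, hits in gene_hits.items():
            hit_sites = {s for s, _ in hits}
            if len(hit_sites) == 1:
                (s,) = hit_sites
                n_hit = len({a for _, a in hits})
                if n_hit > 0.5 * len(achips_of[s]):
                    oracle[s].append(gene)
        assert got == {s: sorted(g) for s, g in oracle.items()}


class TestNsRatio:
    @pytest.mark.parametrize("mean_ns,mean_syn,expected", [
        (15, 17, 0.88),        # ratio-of-means, 2-decimal parity
        (1, 0, None),          # zero synonymous mean -> NA
        (3, 2, 1.5),
        (1.46, 4, 0.37),       # half-up at the .365 boundary
        (12.76, 14.07, 0.91),
        (8, 21.14, 0.38),
    ])
    def test_ratio_of_means(self, mean_ns, mean_syn, expected):
        assert ns_ratio_from_means(mean_ns, mean_syn) == expected

    def test_gene_summary_mean_and_se(self):
        # 2 aChips with (ns, syn) counts (2, 1) and (0, 1) in gene gA
        metas = [_meta("a"), _meta("b")]
        calls = {
            "a": [_call(1, gene="gA", effect="non-synonymous"),
                  _call(4, gene="gA", effect="non-synonymous"),
                  _call(7, gene="gA", effect="synonymous")],
            "b": [_call(7, gene="gA", effect="synonymous")],
        }
        m = build_matrix(calls, metas)
        (s,) = gene_mutation_summary(m)
        assert s.gene_id == "gA" and s.n_achips == 2
        assert s.mean_nonsyn == 1.0 and s.mean_syn == 1.0
        assert s.se_nonsyn == pytest.approx(np.std([2, 0], ddof=1) / np.sqrt(2))
        assert s.se_syn == 0.0
        assert s.ns_ratio == 1.0

    def test_achip_without_gene_mutations_excluded(self):
        metas = [_meta("a"), _meta("b")]
        calls = {"a": [_call(1, gene="gA", effect="non-synonymous")],
                 "b": [_call(50, gene="gB", effect="synonymous")]}
        m = build_matrix(calls, metas)
        by_gene = {s.gene_id: s for s in gene_mutation_summary(m)}
        assert by_gene["gA"].n_achips == 1
        assert by_gene["gA"].mean_nonsyn == 1.0
        assert by_gene["gA"].ns_ratio is None


class TestPerAchipCounts:
    def test_partition_of_detected_nonsynonymous(self, rng):
        m, metas, calls = _random_matrix(rng)
        shared = classify_shared(m, SharedCriterion(5, m.n_samples))
        counts = per_achip_counts(m, shared)
        for meta in metas:
            nonsyn = [c for c in calls[meta.sample_id]
                      if c.effect == "non-synonymous"]
            n_sh = sum(shared.is_shared(c.key) for c in nonsyn)
            assert counts.loc[meta.sample_id, "n_shared"] == n_sh
            assert counts.loc[meta.sample_id, "n_non_shared"] == \
                len(nonsyn) - n_sh

    def test_empty_sample_counts_zero(self):
        metas = [_meta("a"), _meta("b")]
        calls = {"a": [_call(1, effect="non-synonymous")], "b": []}
        m = build_matrix(calls, metas)
        shared = classify_shared(m, SharedCriterion(2, 2))
        counts = per_achip_counts(m, shared)
        assert tuple(counts.loc["b", ["n_shared", "n_non_shared"]]) == (0, 0)
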