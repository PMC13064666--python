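"""Synthetic cosm generator: determinism, population-genetic sanity
(neutral drift is a martingale, selection follows the logistic sweep),
pooled-sampling statistics, and read/error bookkeeping."""

import dataclasses
import math

import numpy as np
import pytest

from evopool.config import SimulationConfig, as_rng
from evopool.simulate import (Lineage, build_predeployment_population,
                              evolve_population, generate_reads,
                              pairwise_identity, sample_isolate_pool,
                              simulate_ancestor, simulate_contaminants,
                              pool_mutation_frequencies)


class TestAncestor:
    def test_deterministic_for_fixed_seed(self, cfg_small, tmp_path):
        from evopool import io as io_mod
        g1, genes1 = simulate_ancestor(cfg_small)
        g2, genes2 = simulate_ancestor(cfg_small)
        assert g1.sequence == g2.sequence
        assert genes1 == genes2
        # byte-identical FASTA / GFF3 on repeated emission
        for i, (g, genes) in enumerate([(g1, genes1), (g2, genes2)]):
            io_mod.write_fasta(g, tmp_path / f"g{i}.fa", seed=cfg_small.seed)
            io_mod.write_gff3(genes, g, tmp_path / f"g{i}.gff3",
                              seed=cfg_small.seed)
        assert (tmp_path / "g0.fa").read_bytes() == (tmp_path / "g1.fa").read_bytes()
        assert (tmp_path / "g0.gff3").read_bytes() == (tmp_path / "g1.gff3").read_bytes()

    def test_gene_layout(self, ancestor):
        genome, genes = ancestor
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 <= s2, "genes overlap"
        assert all((g.end - g.start) % 3 == 0 for g in genes)
        assert sum(g.selection_class == "selected" for g in genes) == 4

    def test_paralog_pair_identity(self, ancestor):
        genome, genes = ancestor
        pair = [g for g in genes if g.paralog_group]
        assert len(pair) == 2
        a, b = pair
        ident = pairwise_identity(genome.sequence[a.start:a.end],
                                  genome.sequence[b.start:b.end])
        assert ident >= 0.80
        assert ident < 1.0

    def test_zero_genes_is_not_an_error(self):
        cfg = SimulationConfig(seed=1, genome_length=2_000, n_genes=0,
                               n_selected_genes=0)
        genome, genes = simulate_ancestor(cfg)
        assert len(genome) == 2_000
        assert genes == []

    def test_genome_too_short_raises(self):
        cfg = SimulationConfig(seed=1, genome_length=1_200, n_genes=10,
                               gene_length=300)
        with pytest.raises(ValueError, match="cannot hold"):
            simulate_ancestor(cfg)


class TestEvolve:
    def test_zero_generations_identity(self, ancestor, cfg_small):
        genome, genes = ancestor
        init = [Lineage("wt", frozenset(), 0.7),
                Lineage("m", frozenset({(5, genome.sequence[5], "A" if genome.sequence[5] != "A" else "C")}), 0.3)]
        out = evolve_population(genome, genes, "pre", cfg_small, init,
                                generations=0)
        assert [(l.lineage_id, l.frequency) for l in out] == \
               [(l.lineage_id, l.frequency) for l in init]

    def test_neutral_drift_is_a_martingale(self, ancestor):
        # mu=0, s=0: E[p_t] = p_0; Monte-Carlo over 1000 replicates
        genome, genes = ancestor
        cfg = SimulationConfig(seed=1, population_size=10_000,
                               mutation_rate=0.0, selection_coefficient=0.0)
        pos = genes[-1].end + 5  # intergenic, selection-free either way
        mut = (pos, genome.sequence[pos], "A" if genome.sequence[pos] != "A" else "C")
        init = [Lineage("wt", frozenset(), 0.7),
                Lineage("m", frozenset({mut}), 0.3)]
        rng = as_rng(202)
        finals = []
        for _ in range(1000):
            out = evolve_population(genome, genes, "pre", cfg, init,
                                    rng=rng, generations=50)
            f = {l.lineage_id: l.frequency for l in out}
            finals.append(f.get("m", 0.0))
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - 0.3) < 3 * se + 1e-12

    def test_selection_follows_logistic_sweep(self, ancestor):
        # deterministic-selection oracle: p_t = p0(1+s)^t / (1-p0+p0(1+s)^t)
        genome, genes = ancestor
        s, p0, t = 0.1, 0.05, 30
        cfg = SimulationConfig(seed=1, population_size=10_000,
                               mutation_rate=0.0, selection_coefficient=s)
        sel_gene = next(g for g in genes if g.selection_class == "selected")
        pos = sel_gene.start + 4
        mut = (pos, genome.sequence[pos], "A" if genome.sequence[pos] != "A" else "C")
        init = [Lineage("wt", frozenset(), 1 - p0),
                Lineage("m", frozenset({mut}), p0)]
        rng = as_rng(303)
        finals = [
            {l.lineage_id: l.frequency
             for l in evolve_population(genome, genes, "pre", cfg, init,
                                        rng=rng, generations=t)}.get("m", 0.0)
            for _ in range(40)]
        mean = float(np.mean(finals))
        growth = (1 + s) ** t
        logistic = p0 * growth / (1 - p0 + p0 * growth)
        assert mean > p0, "selected mutation should beat the neutral mean"
        assert abs(mean - logistic) < 0.08

    def test_frequencies_sum_to_one_with_mutation(self, ancestor, cfg_small):
        genome, genes = ancestor
        init = [Lineage("wt", frozenset(), 1.0)]
        out = evolve_population(genome, genes, "burial", cfg_small,
                                init, rng=as_rng(7), generations=40)
        assert abs(sum(l.frequency for l in out) - 1.0) < 1e-9
        for l in out:
            for pos, ref, alt in l.mutation_set:
                assert 0 <= pos < len(genome)
                assert genome.sequence[pos] == ref != alt

    def test_dormancy_thins_realized_generations(self, ancestor):
        # dormancy_fraction=1 -> ceil(0) = 0 realized generations
        genome, genes = ancestor
        cfg = SimulationConfig(seed=1, dormancy_fraction=1.0)
        init = [Lineage("wt", frozenset(), 1.0)]
        out = evolve_population(genome, genes, "burial", cfg, init,
                                rng=as_rng(1))
        assert len(out) == 1 and out[0].frequency == 1.0


class TestPool:
    def test_single_lineage_takes_whole_pool(self):
        pool = sample_isolate_pool([Lineage("only", frozenset(), 1.0)], 100, 1)
        assert pool == {"only": 100}

    def test_empty_lineage_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sample_isolate_pool([], 100, 1)

    def test_rare_lineage_inclusion_probability(self):
        # P(present) = 1 - (1-0.004)^100, binomial-inclusion oracle
        lins = [Lineage("wt", frozenset(), 0.996),
                Lineage("rare", frozenset(), 0.004)]
        rng = as_rng(42)
        n = 10_000
        hits = sum(sample_isolate_pool(lins, 100, rng)["rare"] > 0
                   for _ in range(n))
        expected = 1.0 - 0.996 ** 100
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_pool_frequency_concentration(self):
        # binomial oracle: within 3 sigma of 0.30 in >= 99% of draws
        lins = [Lineage("wt", frozenset(), 0.70),
                Lineage("m", frozenset(), 0.30)]
        rng = as_rng(43)
        n = 10_000
        tol = 3 * math.sqrt(0.3 * 0.7 / 100)
        inside = sum(abs(sample_isolate_pool(lins, 100, rng)["m"] / 100 - 0.3)
                     <= tol for _ in range(n))
        assert inside / n >= 0.99

    def test_unbiased_pool_frequency(self):
        lins = [Lineage("wt", frozenset(), 0.75),
                Lineage("m", frozenset({(0, "A", "C")}), 0.25)]
        rng = as_rng(44)
        n = 2_000
        freqs = [pool_mutation_frequencies(lins, sample_isolate_pool(lins, 100, rng)
                                           ).get((0, "A", "C"), 0.0)
                 for _ in range(n)]
        freqs = np.asarray(freqs)
        se = freqs.std(ddof=1) / math.sqrt(n)
        assert abs(freqs.mean() - 0.25) < 3 * se


class TestReads:
    def test_error_free_reads_are_reference_substrings(self, ancestor):
        genome, _ = ancestor
        cfg = SimulationConfig(seed=1, genome_length=len(genome),
                               error_rate=0.0, mean_depth=30.0)
        pool = {"wt": 100}
        reads = generate_reads(pool, [Lineage("wt", frozenset(), 1.0)],
                               genome, cfg, 5, "s")
        for r in list(reads)[:200]:
            assert genome.sequence[r.start:r.start + len(r.sequence)] == r.sequence

    def test_read_count_arithmetic(self, ancestor):
        genome, _ = ancestor
        cfg = SimulationConfig(seed=1, genome_length=len(genome),
                               mean_depth=450.0, read_length=150)
        reads = generate_reads({"wt": 100},
                               [Lineage("wt", frozenset(), 1.0)],
                               genome, cfg, 5, "s")
        assert len(reads) == round(450 * len(genome) / 150)

    def test_observed_error_rate_matches_binomial(self):
        cfg = SimulationConfig(seed=1, genome_length=2_000, n_genes=0,
                               n_selected_genes=0, error_rate=0.001,
                               read_length=100, mean_depth=450.0)
        genome, _ = simulate_ancestor(cfg)
        reads = generate_reads({"wt": 100},
                               [Lineage("wt", frozenset(), 1.0)],
                               genome, cfg, 9, "s")
        ref_win = genome.codes[reads.starts[:, None] + np.arange(100)]
        total = reads.seqs.size
        mismatches = int((reads.seqs != ref_win).sum())
        se = math.sqrt(0.001 * 0.999 / total)
        assert abs(mismatches / total - 0.001) < 3 * se

    def test_lineage_mutations_carried_within_span(self, ancestor):
        genome, genes = ancestor
        cfg = SimulationConfig(seed=1, genome_length=len(genome),
                               error_rate=0.0, mean_depth=60.0)
        pos = 1_000
        mut = (pos, genome.sequence[pos],
               "A" if genome.sequence[pos] != "A" else "C")
        lins = [Lineage("m", frozenset({mut}), 1.0)]
        reads = generate_reads({"m": 100}, lins, genome, cfg, 5, "s")
        span = reads.spanning(pos, pos)
        bases = reads.base_at(span, pos)
        from evopool.simulate import _CODE
        assert (bases == _CODE[mut[2]]).all()


class TestPredeployment:
    def test_planted_set_in_band(self, ancestor, cfg_small):
        genome, genes = ancestor
        lins, planted = build_predeployment_population(genome, genes,
                                                       cfg_small)
        freq = {}
        for l in lins:
            for m in l.mutation_set:
                freq[m] = freq.get(m, 0.0) + l.frequency
        assert set(freq) == set(planted)
        assert all(0.25 <= f <= 0.50 for f in freq.values())

    def test_linked_cluster_within_read_span(self, ancestor, cfg_small):
        genome, genes = ancestor
        lins, _ = build_predeployment_population(genome, genes, cfg_small)
        for l in lins:
            if not l.mutation_set:
                continue
            by_gene = {}
            for pos, _, _ in l.mutation_set:
                gid = next(g.gene_id for g in genes if g.contains(pos))
                by_gene.setdefault(gid, []).append(pos)
            assert any(max(ps) - min(ps) < cfg_small.read_length
                       for ps in by_gene.values() if len(ps) >= 2)


class TestContaminants:
    def test_fixed_seed_is_byte_identical(self, cfg_small, tmp_path):
        from evopool import io as io_mod
        for i in range(2):
            table, _, _ = simulate_contaminants(cfg_small)
            io_mod.write_tsv(table.counts, tmp_path / f"c{i}.tsv",
                             seed=cfg_small.seed)
        assert (tmp_path / "c0.tsv").read_bytes() == \
               (tmp_path / "c1.tsv").read_bytes()

    def test_no_site_effect_means_near_identical_composition(self, cfg_small):
        # resampling oracle: with site and achip effects off, pairwise
        # Bray-Curtis within a timepoint is pure multinomial noise
        from evopool.community import bray_curtis
        cfg = dataclasses.replace(cfg_small, site_sigma=0.0, achip_sigma=0.0)
        table, _, _ = simulate_contaminants(cfg, site_sigma=0.0)
        t3 = table.meta.index[table.meta["timepoint"] == 3]
        sub = table.counts[t3]
        dm = bray_curtis(dataclasses.replace(table, counts=sub,
                                             meta=table.meta.loc[t3]))
        observed = dm.condensed_form().mean()

        rng = as_rng(99)
        p = sub.drop(index=table.focal_taxon).sum(axis=1).to_numpy(float)
        p /= p.sum()
        n_reads = int(sub.drop(index=table.focal_taxon).sum(axis=0).mean())
        sims = []
        for _ in range(200):
            a = rng.multinomial(n_reads, p)
            b = rng.multinomial(n_reads, p)
            sims.append(np.abs(a - b).sum() / (a + b).sum())
        bound = np.mean(sims) + 5 * np.std(sims)
        assert observed < bound

    def test_external_taxa_flagged_and_site_bound(self, cfg_small):
        cfg = dataclasses.replace(cfg_small, external_taxon_fraction=0.25)
        table, _, truth = simulate_contaminants(cfg)
        ext = truth[truth["origin"] == "external"]
        assert len(ext) == round(0.25 * cfg.n_taxa)
        pre = table.counts["pre_deployment"]
        assert (pre.loc[ext["taxon"]] == 0).all()

    def test_focal_fraction_declines_with_time(self, cfg_small):
        table, focal, _ = simulate_contaminants(cfg_small)
        by_t = focal.groupby(table.meta["timepoint"]).mean()
        assert by_t.loc[0] > by_t.loc[3] > by_t.loc[10]
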