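"""Seeded end-to-end runner: simulate -> call -> census -> linkage ->
dynamics -> community -> report.

Every stage writes plain-text artifacts stamped with the tool version,
config hash and seed; the final manifest lists each file with its SHA-256
checksum, so two runs with the same config and seed produce identical
manifests. A stage that cannot run under the configured layout (a single
timepoint, or fewer than three sites for covariate correlations) is skipped
with a logged notice rather than an error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import DetectionRule, SharedCriterion, SimulationConfig
from . import census as census_mod
from . import community as community_mod
from . import dynamics as dynamics_mod
from . import io as io_mod
from . import linkage as linkage_mod
from .simulate import simulate_contaminants, simulate_experiment

logger = logging.getLogger("evopool.pipeline")


@dataclass
class RunConfig:
    """Flat configuration for one full pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_frequency: float = 0.01
    min_alt_reads: int = 2
    shared_k: int | None = None          # default: 54/59 scaled to layout
    majority_fraction: float = 0.5
    baseline_timepoint: int = 3
    linkage_min_fraction: float = 0.9
    linkage_min_spanning: int = 10
    write_reads: str = "first"           # none | first | all
    log_level: str = "INFO"

    @property
    def rule(self) -> DetectionRule:
        return DetectionRule(self.min_frequency, self.min_alt_reads)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("sim", {}) or {})
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        return cls(sim=sim, **{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def demo_config(seed: int = 0) -> RunConfig:
    """A compact layout that exercises every stage in seconds."""
    sim = SimulationConfig(seed=seed, genome_length=6_000, n_genes=6,
                           gene_length=300, n_sites=3, n_achips_per_site=6,
                           community_reads=20_000)
    return RunConfig(sim=sim)


def _variant_label(key) -> str:
    pos, ref, alt = key
    return f"{pos + 1}{ref}>{alt}"


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain into ``outdir``; returns the report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(fh)
    seed, chash = config.sim.seed, config.sim.config_hash()
    report: dict = {"version": __version__, "seed": seed,
                    "config_hash": chash, "stages": {}}

    def stage(name, **params):
        logger.info("stage %s: %s", name, params)
        report["stages"][name] = {"params": params}
        return report["stages"][name]

    try:
        # -- simulate -----------------------------------------------------
        st = stage("simulate", **config.sim.to_dict())
        exp = simulate_experiment(config.sim,
                                  keep_reads=(config.write_reads != "none"))
        io_mod.write_fasta(exp.genome, out / "reference.fasta", seed, chash)
        io_mod.write_gff3(exp.genes, exp.genome, out / "genes.gff3",
                          seed, chash)
        pre_af = {}
        for lin in exp.truth.predeployment_lineages:
            for m in lin.mutation_set:
                pre_af[m] = pre_af.get(m, 0.0) + lin.frequency
        io_mod.write_truth_vcf(exp.truth.planted, pre_af, exp.genome,
                               out / "truth_predeployment.vcf", seed, chash)
        lin_df = pd.DataFrame(
            [{"lineage_id": l.lineage_id, "frequency": l.frequency,
              "n_mutations": len(l.mutation_set)}
             for l in exp.truth.predeployment_lineages])
        io_mod.write_tsv(lin_df, out / "truth_lineages.tsv", seed, chash,
                         index=False)
        pools = pd.DataFrame(
            [{"sample_id": s.sample_id, "lineage_id": lid, "isolates": n}
             for s in exp.samples for lid, n in sorted(s.pool.items()) if n])
        io_mod.write_tsv(pools, out / "truth_pools.tsv", seed, chash,
                         index=False)
        io_mod.write_tsv(exp.truth.covariates, out / "site_covariates.tsv",
                         seed, chash)

        reads_written = []
        if config.write_reads != "none":
            targets = (exp.samples[:1] if config.write_reads == "first"
                       else exp.samples)
            for s in targets:
                rs = exp.reads_by_sample[s.sample_id]
                io_mod.write_sam(rs, exp.genome,
                                 out / f"reads_{s.sample_id}.sam", seed, chash)
                io_mod.write_fastq(rs, out / f"reads_{s.sample_id}.fastq",
                                   seed, chash)
                reads_written.append(s.sample_id)
        st["reads_written"] = reads_written

        # -- call ---------------------------------------------------------
        st = stage("call", min_frequency=config.min_frequency,
                   min_alt_reads=config.min_alt_reads)
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        for s in exp.samples:
            io_mod.write_vcf(exp.calls_by_sample[s.sample_id], exp.genome,
                             calls_dir / f"{s.sample_id}.vcf", seed, chash)
        st["n_samples"] = len(exp.samples)

        # -- census -------------------------------------------------------
        matrix = census_mod.build_matrix(exp.calls_by_sample, exp.metas,
                                         config.rule)
        n = matrix.n_samples
        crit = (SharedCriterion(config.shared_k, n) if config.shared_k
                else SharedCriterion.scaled(n))
        st = stage("census", k=crit.k, n=crit.n,
                   majority_fraction=config.majority_fraction)
        shared = census_mod.classify_shared(matrix, crit)
        freq_out = matrix.frequencies.copy()
        freq_out.index = [_variant_label(k) for k in freq_out.index]
        io_mod.write_tsv(freq_out, out / "matrix.tsv", seed, chash)
        shared_df = pd.DataFrame({
            "variant": [_variant_label(k) for k in matrix.frequencies.index],
            "gene_id": matrix.variant_info["gene_id"].to_numpy(),
            "effect": matrix.variant_info["effect"].to_numpy(),
            "n_detected": matrix.detected.sum(axis=1).to_numpy(),
            "shared": [shared.is_shared(k) for k in matrix.frequencies.index],
        })
        io_mod.write_tsv(shared_df, out / "shared_mutations.tsv", seed, chash,
                         index=False)
        venn_rows = []
        for t in sorted(set(matrix.samples["timepoint"])):
            for sub, cnt in census_mod.venn_partition(matrix, t).items():
                venn_rows.append({"timepoint": t,
                                  "sites": "+".join(sorted(sub)),
                                  "n_variants": cnt})
        io_mod.write_tsv(pd.DataFrame(venn_rows), out / "venn_regions.tsv",
                         seed, chash, index=False)
        summaries = census_mod.gene_mutation_summary(matrix)
        io_mod.write_tsv(pd.DataFrame([dataclasses.asdict(s)
                                       for s in summaries]),
                         out / "gene_summary.tsv", seed, chash, index=False)
        counts = census_mod.per_achip_counts(matrix, shared)
        io_mod.write_tsv(counts, out / "per_achip_counts.tsv", seed, chash)
        unique = census_mod.site_unique_genes(matrix,
                                              config.majority_fraction)
        io_mod.write_tsv(pd.DataFrame(
            [{"site": s, "gene_id": g} for s, gs in unique.items()
             for g in gs]), out / "site_unique_genes.tsv", seed, chash,
            index=False)
        st.update(n_variants=len(matrix.frequencies),
                  n_shared=len(shared.shared),
                  n_planted=len(exp.truth.planted))

        # -- linkage ------------------------------------------------------
        st = stage("linkage", min_fraction=config.linkage_min_fraction,
                   min_spanning=config.linkage_min_spanning)
        if reads_written:
            rs = exp.reads_by_sample[reads_written[0]]
            span = config.sim.read_length
            shared_sorted = sorted(shared.shared)
            pairs = [(a, b)
                     for i, a in enumerate(shared_sorted)
                     for b in shared_sorted[i + 1:]
                     if abs(a[0] - b[0]) < span]
            records = linkage_mod.pairwise_linkage(rs, pairs)
            io_mod.write_tsv(pd.DataFrame(
                [{"variant_a": _variant_label(r.variant_a),
                  "variant_b": _variant_label(r.variant_b),
                  "spanning": r.reads_spanning_both,
                  "both_alts": r.reads_with_both_alts,
                  "one_alt": r.reads_with_exactly_one_alt,
                  "linkage_fraction": r.linkage_fraction}
                 for r in records]), out / "linkage.tsv", seed, chash,
                index=False)
            groups = linkage_mod.linked_groups(
                records, config.linkage_min_fraction,
                config.linkage_min_spanning)
            st["n_pairs"] = len(records)
            st["group_sizes"] = sorted((len(g) for g in groups),
                                       reverse=True)
            para = [g for g in exp.genes if g.paralog_group]
            if para:
                assigns = linkage_mod.assign_paralog_reads(rs, para,
                                                           exp.genome)
                io_mod.write_tsv(pd.DataFrame(
                    [{"read_id": a.read_id,
                      "assigned": a.assigned_gene_id,
                      "mismatches": ",".join(map(str,
                                                 a.mismatches_per_candidate))}
                     for a in assigns]), out / "paralog_assignments.tsv",
                    seed, chash, index=False)
                st["n_paralog_reads"] = len(assigns)
        else:
            logger.info("linkage skipped: no reads retained")
            st["skipped"] = "no reads retained"

        # -- dynamics -----------------------------------------------------
        timepoints = sorted(set(matrix.samples["timepoint"]))
        st = stage("dynamics", baseline=config.baseline_timepoint)
        if len(timepoints) < 2:
            logger.info("dynamics skipped: single timepoint %s", timepoints)
            st["skipped"] = f"single timepoint {timepoints}"
        else:
            shift_rows = []
            for t in timepoints:
                if t == config.baseline_timepoint:
                    continue
                shifts = dynamics_mod.baseline_shift(
                    matrix, t, config.baseline_timepoint)
                df = dynamics_mod.shifts_to_frame(shifts)
                df.insert(0, "timepoint", t)
                shift_rows.append(df)
            shifts_df = pd.concat(shift_rows, ignore_index=True)
            shifts_df["variant"] = shifts_df["variant"].map(_variant_label)
            io_mod.write_tsv(shifts_df, out / "frequency_shifts.tsv",
                             seed, chash, index=False)

            anova_rows, tukey_rows = [], []
            for key in shared.shared:
                data = pd.DataFrame({
                    "frequency": matrix.frequencies.loc[key],
                    "site": matrix.samples["site"],
                    "timepoint": matrix.samples["timepoint"]})
                tbl = None
                for factors, inter in ((["site", "timepoint"], True),
                                       (["site", "timepoint"], False),
                                       (["site"], False)):
                    try:
                        tbl = dynamics_mod.anova(data, "frequency", factors,
                                                 interaction=inter)
                        break
                    except ValueError:
                        continue
                if tbl is None:
                    logger.info("anova skipped for %s: layout too small", key)
                    continue
                for term, row in tbl.table.iterrows():
                    anova_rows.append({"variant": _variant_label(key),
                                       "term": term, **row.to_dict()})
                means = data.groupby("site")["frequency"].mean().to_dict()
                sizes = data.groupby("site")["frequency"].size().to_dict()
                for tr in dynamics_mod.tukey_hsd(means, tbl.residual_ms(),
                                                 tbl.residual_df(), sizes):
                    tukey_rows.append({"variant": _variant_label(key),
                                       "site_a": tr.group_a,
                                       "site_b": tr.group_b,
                                       "mean_diff": tr.mean_diff,
                                       "q": tr.q, "p": tr.p})
            io_mod.write_tsv(pd.DataFrame(anova_rows), out / "anova.tsv",
                             seed, chash, index=False)
            io_mod.write_tsv(pd.DataFrame(tukey_rows), out / "tukey.tsv",
                             seed, chash, index=False)

            if matrix.samples["site"].nunique() >= 3:
                t_last = timepoints[-1]
                res = dynamics_mod.abiotic_correlation(
                    matrix, exp.truth.covariates, t_last)
                corr = dynamics_mod.correlations_to_frame(res)
                corr["variant"] = corr["variant"].map(_variant_label)
                io_mod.write_tsv(corr, out / "abiotic_correlations.tsv",
                                 seed, chash, index=False)
            else:
                logger.info("correlations skipped: fewer than 3 sites")
                st["correlations_skipped"] = "fewer than 3 sites"

        # -- community ----------------------------------------------------
        st = stage("community", n_taxa=config.sim.n_taxa)
        table, focal, taxon_truth = simulate_contaminants(config.sim)
        io_mod.write_tsv(table.counts, out / "community_counts.tsv",
                         seed, chash)
        io_mod.write_tsv(taxon_truth, out / "community_truth.tsv",
                         seed, chash, index=False)
        io_mod.write_tsv(focal.to_frame(), out / "focal_fraction.tsv",
                         seed, chash)
        io_mod.write_tsv(community_mod.shannon(table).to_frame(),
                         out / "shannon.tsv", seed, chash)
        dm = community_mod.bray_curtis(table)
        io_mod.write_tsv(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                         out / "braycurtis.tsv", seed, chash)
        ord_res = community_mod.pcoa(dm)
        io_mod.write_tsv(ord_res.coordinates, out / "pcoa_coordinates.tsv",
                         seed, chash)
        pre = table.counts["pre_deployment"]
        achip_cols = table.meta.index[table.meta["site"] != "pre"]
        site_tables = {
            site: table.counts[table.meta.index[(table.meta["site"] == site)]]
            for site in sorted(table.meta.loc[achip_cols, "site"].unique())}
        attr = community_mod.attribute_sources(site_tables, pre,
                                               table.focal_taxon)
        io_mod.write_tsv(attr.percentages, out / "source_attribution.tsv",
                         seed, chash)
        st["pre_deployment_pct_mean"] = float(
            attr.percentages["pre_deployment"].mean())

        # -- report -------------------------------------------------------
        files = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name not in
                       ("manifest.json", "run.log"))
        report["manifest"] = {str(p.relative_to(out)): io_mod.sha256_file(p)
                              for p in files}
        with open(out / "manifest.json", "w") as fhj:
            json.dump(report, fhj, indent=2, sort_keys=True)
        return report
    except Exception as e:  # noqa: BLE001 - abort with stage context
        done = list(report["stages"])
        current = done[-1] if done else "setup"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {e}") from e
    finally:
        logger.removeHandler(fh)
        fh.close()
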