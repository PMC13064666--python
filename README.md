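# evopool

Pooled-isolate resequencing toolkit for **in situ experimental evolution**
in buried soil chambers ("aChips"). A clonal soil bacterium is grown in
autoclaved carrier soil, sealed into membrane-bounded chambers, buried at
several field sites, and periodically recaptured as 100-isolate pools that
are shotgun-sequenced against the ancestral genome. `evopool` implements
the full computational chain for such a study, plus a synthetic cosm
generator that makes every stage testable without any download:

- **simulate** — ancestral genome with diverged paralogous gene copies;
  two-phase Wright-Fisher population dynamics (lab incubation building
  mid-frequency standing variation, burial with dormancy adding rare de
  novo mutations); 100-isolate pooled sampling; pre-aligned error-bearing
  reads at ~450×; a contaminant community drifting by site and time; full
  machine-readable truth.
- **call** — per-position pileup, pool-aware variant calling
  (`f = alt_reads / depth`, defaults `min_frequency = 0.01`,
  `min_alt_reads = 2`), strand-aware synonymous/non-synonymous annotation.
- **census** — variant × sample matrix; *shared mutations* via a k-of-n
  prevalence rule (e.g. detected in ≥ 54 of 59 pools); once-per-site Venn
  partitions; site-unique-gene parallelism; per-gene N:S summaries
  (ratio-of-means, NA when the synonymous mean is zero); per-chip counts.
- **linkage** — single-read co-occurrence between variant pairs
  (`linkage_fraction = both-alt reads / spanning reads`), single-linkage
  grouping, and paralog best-match verification of mutated reads.
- **dynamics** — frequency shifts in percentage points against the pooled
  baseline-timepoint mean; sequential-SS fixed-effects ANOVA; Tukey's HSD
  from the studentized-range distribution; per-variant Pearson correlations
  with site abiotic covariates (zinc, pH, organic matter).
- **community** — focal-read fractions, Shannon diversity (natural log),
  Bray–Curtis distances, PCoA, and source attribution of non-focal taxa
  (pre-deployment carrier soil / other site / site-exclusive).

Key quantities in the field's notation: pool frequency of a mutation is a
multiple of 1/pool_size (so a 100-isolate pool has a **1% detection
floor**); a variant is **shared** iff detected in ≥ k of n pools; the
**N:S ratio** per gene is mean non-synonymous over mean synonymous
mutation counts per chip; linkage is evidenced only by co-occurrence **on
single sequencing reads**.

## Worked example

```python
import evopool as ep
from evopool.config import SharedCriterion

exp = ep.simulate_experiment(seed=3)          # 5 sites x 12 aChips, 450x
matrix = ep.build_matrix(exp.calls_by_sample, exp.metas)
crit = SharedCriterion.scaled(matrix.n_samples)   # 54/59 -> 55/60
shared = ep.classify_shared(matrix, crit)
print(crit)
print(len(matrix.frequencies), len(shared.shared), len(exp.truth.planted))
print(set(shared.shared) == set(exp.truth.planted))
```

prints

```
SharedCriterion(k=55, n=60)
75 10 10
True
```

i.e. the 60 sequenced pools yielded 75 distinct called variants, of which
exactly the 10 planted pre-deployment mutations (the standing variation
installed at 25–50% frequency before burial) pass the 55-of-60 prevalence
rule — the remaining 65 are rare post-burial de novo calls private to
single chips, just as a k-of-n census should separate them.

The same chain is available from the shell:

```bash
evopool run --seed 3 --outdir results/demo
evopool call --reads reads.sam --ref ref.fasta --genes genes.gff3 \
             --min-af 0.01 --min-alt 2 --out calls.vcf
```

`evopool run` writes a self-describing results directory (FASTA/GFF3/SAM/
FASTQ/VCF/TSV, each stamped with version, config hash and seed) plus a
`manifest.json` of SHA-256 checksums; identical config + seed reproduces
the manifest byte for byte.

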