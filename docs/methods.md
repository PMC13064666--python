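# Methods

`evopool` models a buried-chamber ("aChip") experimental-evolution study: a
clonal soil bacterium is incubated in autoclaved carrier soil, sealed into
membrane-bounded chambers, buried at several farm sites, and periodically
recaptured as 100-isolate pools that are shotgun-sequenced against the
ancestral genome. The package provides both the analysis chain for such data
(pileup, pool-aware variant calling, effect annotation, cross-sample census,
read-backed linkage, frequency statistics, community analytics) and a
synthetic cosm generator that makes every stage testable end to end without
any external data.

## The population model

Evolution is simulated at the level of *lineages*: haplotype classes defined
by the set of substitutions they carry relative to the ancestor. Each
realized generation applies Wright-Fisher multinomial resampling of `N`
individuals with multiplicative fitness `(1+s)` per mutation residing in a
selected gene, then seeds `Poisson(mu*N)` de novo substitutions uniformly on
the genome, each founding a new lineage at frequency `1/N`.

Generations are the clock. The study the generator emulates reports calendar
time (3/10/24 months) but no generation counts, so calendar time maps to
generations only through configuration: a full 24-month burial corresponds
to `generations_burial` (default 60) generations before dormancy, scaled
linearly for intermediate retrievals. Dormancy is modeled as uniformly
skipped generations: the burial phase realizes only
`ceil((1 - dormancy_fraction) * generations)` of them (default fraction 0.8,
so a 24-month burial realizes 12 generations). This is the simplest
mechanism producing the observed phenotype - an almost-static population
that still accrues a few rare variants - without tracking spore states.

Two effective sizes are used: `population_size` (1e4) for the carrier-soil
growth phase and `burial_population_size` (1e3) inside a chamber holding
about a gram of soil. The smaller burial `N` lets de novo mutations enter at
0.1% and occasionally drift to pool-detectable frequency, reproducing the
"fewer than ten novel mutations per pool, almost all below 10%" regime.

### Pre-deployment standing variation

The default experiment does not obtain its carrier-soil population by
running the pre-phase simulator blind. A Wright-Fisher phase tuned to push
selected sweeps into a target band necessarily leaves mid-sweep stragglers
at intermediate frequencies; those are inherited by every chamber and are
detected in an unpredictable subset of pools, which makes "the planted set"
ill-defined. Instead `build_predeployment_population` constructs the
standing variation explicitly: a wild-type lineage plus two mutant
haplotypes, each drawn at a frequency inside the 25-50% band, carrying
mutations concentrated in the selected genes (zinc-uptake paralog copy 2, a
zinc-independent folate-branch gene, a cell-division gene), with three of
each gene's mutations clustered inside a single read span so that single-read
linkage has substrate. The union of the mutant haplotypes is the designated
pre-deployment truth set. The general two-phase simulator
(`evolve_population`) remains available and is exercised by its own tests
(neutral drift is a martingale; selected sweeps track the deterministic
logistic trajectory).

### Abiotic coupling

Each site draws abiotic covariates spanning realistic farm-soil ranges
(zinc 0.8-3.2 ppm, pH 5.6-7.1, organic matter 2.2-4.9%). During burial the
fitness of mutations in the zinc-responsive gene is `-abiotic_beta *
zscore(zinc_site)` (default beta 0.02), so populations at low-zinc sites
push those mutations up and high-zinc sites push them down, by roughly +/-8
percentage points over 24 months - the magnitude of the site-dependent
shifts the census stage is meant to detect, and the planted signal behind
the negative zinc correlation check.

## Pooled sampling and sequencing

A retrieval draws `pool_size` (100) isolates multinomially by lineage
frequency; the pool frequency of any mutation is therefore a multiple of
1/100, which fixes the design's detection floor at 1% and motivates the
default caller threshold (`min_frequency = 0.01`, `min_alt_reads = 2`; the
second suppresses singleton errors at ~450x). Reads are emitted pre-aligned
and ungapped with uniform starts at `mean_depth` (450x, matching the study's
423x/509x averages), each drawn from a lineage proportional to its pool
count, carrying that lineage's mutations, then per-base substitution errors
at 0.001. Error sites are drawn as a binomial count of distinct positions;
the collision deficit (about half of n_err/total_bases, relatively) is
orders of magnitude below test tolerances. Alignment, indels, quality
models, GC bias and wrapping reads on circular genomes are deliberately out
of scope: none is part of the method under study.

A note on attainable accuracy: the read-level estimate of a pool frequency
`p` at depth `D` is `Binomial(D, p)/D`, with standard error
`sqrt(p(1-p)/D)` - 2.0-2.4 percentage points at 450x for the 25-50% band.
The probability of landing within +/-3 points of truth is therefore 0.80-0.86
per mutation in that band, an information-theoretic property of the depth,
not a defect of the caller; the acceptance suite reports the honest
fraction. Depths near 1000x would be needed for a 95% within-3-point rate.

## The census layer

The mutation matrix is the union of per-sample calls (variant x sample
frequencies plus detection flags under one rule applied uniformly). The
shared/non-shared split is a plain k-of-n prevalence rule; the reference
rule (54 of 59) is rescaled to any layout by `ceil(n * 54/59)`. Venn
partitions count a variant once per site ("detected in at least one of that
site's chips"); site-unique genes operationalize "mutated in most chips at
exactly one site" with a configurable majority fraction (default 0.5). N:S
summaries are ratio-of-means (not mean-of-ratios), computed over the chips
that possess at least one mutation of either class in the gene, with SE =
sd/sqrt(n) and half-up rounding to two decimals for report parity; a zero
synonymous mean yields NA.

## Linkage and paralogs

Linkage evidence is strictly single-read co-occurrence: for a variant pair,
the fraction of reads spanning both positions that carry both alternate
alleles. No statistical phasing bridges unspanned pairs. Note the
denominator includes wild-type reads, so a linked haplotype at 30%
population frequency shows a fraction near 0.3; fractions near 1 identify
sites where the alternate alleles travel together in essentially all
carriers. Groups are single-linkage components over pairs with fraction >=
0.9 and >= 10 spanning reads (declared defaults; configurable). The paralog
best-match check compares each read gap-free against every copy in its
paralog group at matched within-gene offsets and assigns the unique
minimum-mismatch copy, with ties reported as AMBIGUOUS; copies are generated
without indels, which is the stated limitation of the gap-free comparison.

## Statistics

Frequency shifts are reported in percentage points against the pooled
baseline-timepoint mean (all sites), the baseline the study design trusts.
ANOVA is fixed-effects OLS with sequential (type I) sums of squares - exact
on balanced layouts, documented sequential fitting otherwise - with
interaction by default for two factors; all-equal responses yield a flagged
NaN F rather than an error. Tukey's HSD takes q from the studentized-range
distribution with (k, residual df); at k = 2 it reduces to the ANOVA p
exactly. Covariate correlations are per-variant Pearson r against the
sample's site covariate with two-sided t-transform p-values; zero-variance
inputs are flagged, and a Benjamini-Hochberg adjustment is available but off
by default (per-mutation reporting, matching the study's presentation).
Calibration uses a dedicated null simulator (pooling plus sequencing noise
around a constant frequency, no site effect); the one-way F-test's type-I
rate is checked against 0.05 over 200 datasets.

## Community analytics

Shannon diversity uses the natural log; diversity, Bray-Curtis and PCoA
exclude the focal species by default because the questions concern the
contaminant community around it (a flag includes it). PCoA is classical
scaling via scikit-bio; negative eigenvalues are reported and excluded from
the variance-explained denominator. Source attribution classifies each
non-focal taxon per site in rule order - pre-deployment if detected in the
carrier-soil table, else other-site, else site-exclusive - and tallies
read-weighted percentages per site's chip set (per-chip weighting is a
trivial variation the caller can apply by subsetting).

The contaminant generator draws baseline log-normal abundances with strong
dominance (sigma 2.0) that relaxes over time (survivors of autoclaving
growing back, so alpha diversity rises) while site-specific log-normal
perturbations grow over time (so sites separate in ordination); the focal
share declines on the logit scale. The pre-deployment column holds expected
counts floored at one read per present taxon - the carrier soil is treated
as exhaustively characterized - so presence/absence truth is exact and the
zero-external-taxon configuration attributes exactly 100% of non-focal
reads to the carrier soil. What the generator does not emulate: taxonomic
misclassification, compositional interactions between taxa, and
sequencing-effort differences between samples; conclusions about real
kraken-style tables should be drawn accordingly.

## Problem sizes and numerics

The default synthetic experiment uses a 20 kb genome with 20 genes (600 bp,
4 selected) so that the full 5 sites x 12 chips x 450x chain runs in
seconds per replicate while keeping every per-base rate (depth, error,
detection floor) at study scale; the per-gene mutation density is
correspondingly higher than a real 5-Mb genome's. Internal coordinates are
0-based half-open everywhere, converted to 1-based exactly once at the
GFF3/SAM/VCF boundary. Lineage frequencies are validated to sum to 1 within
1e-9; largest-remainder apportionment converts frequencies to integer
counts when a phase starts. All randomness flows through
`numpy.random.Generator` seeded from the configuration, and identical
config plus seed yields byte-identical outputs (checksummed manifests).

## Known limitations

Substitutions only (no indels or structural variants); no read mapping or
quality modeling; gap-free paralog comparison; sequential-SS ANOVA rather
than the study's unpublished model; linkage restricted to read-span pairs;
the 1% floor means sub-percent variants are invisible by design, as in the
pooled-isolate protocol itself.
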