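# Methods

## Problem setting

Intermediate wheatgrass (IWG) is an outcrossing perennial grass being
domesticated as a grain crop. Each genebank accession is a heterogeneous
population; a *genet* is one genetically distinct plant from it. The package
infers which accessions founded an improved breeding population from two
evidence streams: genotype-based assignment of modern genets to candidate
accessions, and reconstruction of a historical phenotype-based selection.
Both streams are exercised on packaged transcriptions of the historical
evaluation tables and on synthetic data whose generative process mirrors the
breeding history.

## Genotype model and calling

IWG is allohexaploid, but the marker data the inference runs on are
diploid-style biallelic SNPs; genotypes are therefore alt-allele dosages in
{0, 1, 2}, with missing calls explicit. Raw GBS evidence is a pair of read
counts (ref, alt) per genet-locus. Calling is depth-gated:

- ≥ 1 read of each allele → heterozygote (dosage 1);
- only one allele observed, with ≥ 4 reads → homozygote (0 or 2);
- otherwise missing.

When both alleles are observed the heterozygote rule takes precedence (so
ref = 4, alt = 1 is called het, not hom-ref). This precedence is a fixed
convention: some rule ordering must be chosen for determinism, and requiring
literally *any* contrasting read to veto a homozygote is the conservative
reading of a two-contrasting-reads heterozygote rule.

Marker filters keep loci that are strictly biallelic, have folded minor
allele frequency strictly greater than 0.05 (computed over non-missing calls
only), and are called in at least 30% of genets; genets missing more than 95%
of calls are removed. The strict/inclusive boundaries follow the stated
rules exactly ("greater than 0.05", "minimum of 30%", "more than 95%").
Filter reports attribute each removed locus to the first failing rule, in the
order non-biallelic → call rate → MAF.

## Composite profiles, distance, and assignment

An accession's composite profile is the per-locus mean dosage of its member
genets over non-missing calls (missing where no member is called). Pooling
by mean dosage, rather than by summing reads, keeps a deeply sequenced genet
from dominating the composite.

Distance between two dosage vectors is Euclidean over their shared
non-missing loci, rescaled by `sqrt(n_total / n_shared)` — the missing-data
convention of R's `dist`, which this package mirrors so that sparse and
complete pairs are on a common scale. With complete data it reduces exactly
to plain Euclidean distance. Pairs sharing no locus get a missing distance
and a logged warning.

Queries are assigned to the reference accession with minimal profile
distance; ties break lexicographically on accession id and are flagged. A
secondary per-genet mode ranks accessions by the minimum distance over their
individual member genets.

Leave-one-out masking validation removes each genet from its own accession's
composite before assigning it. Excluding the masked genet is essential:
with ~6 genets per accession, leaving it in the composite leaks roughly a
sixth of the answer into the reference and inflates accuracy. Accessions
with a single genotyped genet cannot be queried this way and are tallied
separately.

## Founder counting

Candidate founders are first restricted to accessions available to the
breeding program: accessions *collected* strictly after the cutoff year
(default 1990) are excluded, donated accessions are exempt, and unknown
acquisition years are retained with a logged note (exclusion requires
positive evidence). Assignments are tallied per accession; the top-k set
(default k = 20, the recorded head-count of the polycross) is ordered by
descending count then id, with rank-k ties all included and logged rather
than silently truncated. Accessions with ≤ 10 assignments are reported as
weakly supported singletons. Cross-source founder sets are compared by full
Venn-region decomposition, whose exclusive region cardinalities always sum to
the union size.

## Historical phenotype computations

Traits: 100-seed weight (g; arithmetic mean of exactly three 100-seed
samples), seed-set rating (%, 100 × clean seed mass / unthreshed head mass
from 10 heads), and seed yield (g) per 10 heads.

Combined-year summaries compute each year's mean over the accessions recorded
that year, then average the year means with equal weight. Equal year
weighting is the package default because the drought-year (1988) yield column
exists for only 10 of the 20 selected accessions; pooling all cells would
weight the wet year twice as heavily (pooled averaging is available as an
option and yields 2.59 rather than 2.67 g on the packaged table).

Subset reconstruction minimizes the weighted relative squared deviation

```
F(S) = Σ_t w_t · ( (mean_t(S) − target_t) / target_t )²
```

with equal default weights. Relative deviations put a 0.5 g trait and a 45%
trait on the same footing; the historical search was informal, so the loss is
a package design choice. The search is exhaustive when the number of
candidate subsets is ≤ 10⁶; otherwise a greedy build-up is refined by
best-improvement pairwise swaps with 10 seeded random restarts, which matches
the exhaustive optimum on all tested small instances. Locked accessions are
always included.

The packaged molecular-evidence table stores its single recorded yield value
under 1989 (its printed year columns are collapsed in the source); no
quantitative check is anchored on that table's footer, which does not
recompute from its body.

## Passport reliability

A passport record supports a country-of-origin claim only if it names a
present-day state ("Former USSR" and variants are too coarse) and the
collection site is not a garden or institute (a botanical-garden sample
locates the seed, not the wild population). Origin summaries count reliable
records per country and tally everything else as unreliable, so counts always
partition the queried set. The per-country tallies across *all* evidence
tables depend on unstated curatorial judgments; the package reproduces the
selection-table count (13 Russian of 20) and exposes the reliability rule as
data (a garden flag plus the non-specific-origin list) rather than hard-coded
conclusions.

## Synthetic data generator

The generator emulates, stage by stage, the process the analysis assumes:

- **Accession divergence.** Per locus, an ancestral minor-allele frequency is
  drawn uniformly from (0.05, 0.5] and randomly unfolded; each accession's
  frequency is Beta-distributed with mean p and variance Fst·p(1−p)
  (Balding–Nichols). Default Fst = 0.15 keeps most genetic variance within
  accessions, consistent with the reported structure of the real collection
  (> 70% within-accession variation).
- **Genets.** Dosages are Binomial(2, q) per locus — Hardy–Weinberg within
  accession, independent loci.
- **Polycross.** Each progeny draws two distinct parents uniformly (no
  selfing; mate choice uniform, as the crossing design aimed for pollination
  among all entries), one Mendelian gamete per parent, loci unlinked; progeny
  become the next cycle's parent pool. Defaults: 2 cycles of 300 progeny,
  matching the remnant material's two recombination cycles. The
  founder-recovery benchmark intermates 3 genets per selected accession,
  matching the three root segments dug per selected nursery row.
- **GBS observation.** Total depth per genet-locus is Poisson(mean depth 8),
  zeroed with dropout probability 0.3 independently of locus and genet; alt
  reads are Binomial(depth, dosage/2).
- **Phenotypes.** value = trait mean + accession effect + year effect +
  accession×year interaction + noise, with per-trait scaling and an explicit
  per-(trait, year) missingness pattern to mimic partially recorded columns.

What it deliberately does not model: linkage and recombination maps (the
inference uses genome-wide distance only), hexaploid subgenomes, selection
between polycross cycles (off by default so founder-recovery baselines are
neutral drift), structured missingness, genotyping error beyond the binomial
read-sampling process, and admixture between genebank accessions prior to
sampling. Passing synthetic benchmarks therefore demonstrates correctness of
the inference machinery under its own assumptions, not robustness to
regeneration admixture or field mislabeling in real collections.

## Benchmarks and problem sizes

The leave-one-out benchmark simulates 50 accessions × 6 genets at 2,000 loci
(Fst 0.15, depth 8, 30% dropout), applies calling and filters, and validates
assignment; 10 replicates are averaged. The founder-recovery benchmark uses
139 candidate accessions with 20 true founders, two polycross cycles and 300
descendants, and scores the precision of the inferred top-20 set. Both
finish in seconds on one CPU; sizes were chosen to match the documented
breeding design (139 evaluated accessions, 20 selected, ~6 genets per
genebank accession).

## Numerical choices

- Missing dosages are NaN in float matrices; all distance algebra uses
  mask-aware matrix products, with tiny negative round-off clipped at zero
  before the square root and pairwise symmetry enforced by averaging.
- Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); identical configuration including seed gives
  bit-identical artifacts, which the pipeline manifest (sha256 per artifact)
  makes checkable.
- Degenerate inputs: zero-shared-locus pairs → missing distance plus warning;
  accessions with no genotyped member → error; empty assignment lists →
  error; loci with zero calls fail the MAF filter by convention.

## Known limitations

- The diploid dosage model discards allele-dosage information a hexaploid
  caller could extract.
- Availability filtering trusts passport acquisition metadata; mislabeled
  acquisition modes propagate directly into the candidate pool.
- The reconstruction objective can have near-ties: materially different
  subsets may fit the recorded targets almost equally well, which is a
  property of the historical evidence, not of the solver.
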