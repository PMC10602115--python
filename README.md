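# iwgtrace

Founder inference for intermediate wheatgrass (*Thinopyrum intermedium*)
germplasm improved for Kernza® grain production.

Modern food-grade intermediate wheatgrass (IWG) descends from a 1980s
recurrent-selection program that intermated ~20 genebank plant introductions
(PIs) in an open polycross, but the list of selected parents was lost.
`iwgtrace` implements the two complementary lines of evidence used to recover
those founders, as a tested, reproducible pipeline:

1. **Molecular tracing.** Genotyping-by-sequencing (GBS) genotypes of modern
   breeding material and of candidate genebank accessions are re-called with
   depth-gated rules, filtered, pooled into composite accession profiles, and
   each modern genet is assigned to its nearest accession by a missing-data-
   scaled Euclidean distance. Assignment counts, restricted to accessions that
   were actually available to the program, yield the inferred founder set.
2. **Historical reconstruction.** Recovered nursery records give two years of
   seed-yield component data (100-seed weight, seed-set rating, yield per 10
   heads) plus the recorded trait averages of the selected parents; a subset
   search recovers the accession combination that best matches those targets.

A first-class synthetic-data module simulates the whole generative process —
Balding–Nichols accession divergence, Hardy–Weinberg genets, multi-cycle
polycross intermating, and a Poisson-depth GBS observation layer — so every
stage is testable end to end without external data. The published evaluation
tables (the 20 historically inferred parents, the 14 molecularly implicated
accessions, and the 10 genebank-wide additions) ship as packaged TSV fixtures.

## The core statistic

For genets/profiles *x*, *y* genotyped as alt-allele dosages in {0, 1, 2} at
*L* biallelic loci, the relationship distance is

```
d(x, y) = sqrt( L / |S| · Σ_{j ∈ S} (x_j − y_j)² ),   S = loci called in both
```

(the missing-data convention of R's `dist`). An accession's composite profile
is the per-locus mean dosage of its member genets. A query is assigned to the
accession with minimal d; assignment quality is estimated by leave-one-out
masking validation, where each genebank genet is removed from its accession's
composite and re-assigned from genotype alone.

Genotypes are re-called from allele depths before any of this: a homozygote
needs ≥ 4 reads of a single allele, a heterozygote ≥ 1 read of each allele,
anything else is missing. Markers are kept if strictly biallelic, folded
minor-allele frequency > 0.05, and called in ≥ 30% of genets; genets with
> 95% missing data are dropped.

## Worked example

```python
from iwgtrace import datasets, trait_summary, origin_summary, intersect_sources
from iwgtrace.datasets import polycross1_source_sets, table1_passports
from iwgtrace.synthetic_data import SimConfig
from iwgtrace.workflows import loo_benchmark

ts = trait_summary(datasets.table1_phenotypes())
for trait, mean in ts.means.items():
    print(f"{trait:>24s}  {mean:.3f}")
print("Russia count:", origin_summary(table1_passports()).counts["Russia"])
print("core founders:", sorted(intersect_sources(polycross1_source_sets()).common))
res = loo_benchmark(SimConfig(seed=1))
print(f"LOO accuracy: {res.accuracy:.4f} over {res.n_queries} masked genets")
```

prints

```
   hundred_seed_weight_g  0.496
     seed_set_rating_pct  44.775
    yield_per_10_heads_g  2.666
Russia count: 13
core founders: ['PI273732', 'PI286118', 'PI314054', 'PI316122', 'PI440004', 'PI440015']
LOO accuracy: 1.0000 over 300 masked genets
```

The first block is the combined-year trait means of the 20 reconstructed
polycross parents — 0.496 g seed weight, 44.8% seed set, and 2.67 g per 10
heads against the recorded selection targets of 0.495 g / 45% / 2.5 g (the
yield mean uses equal year weighting because the drought-year column was only
partially recorded). Thirteen of the twenty parents have reliable Russian
origin, and six PI accessions are supported by *every* data source — the
genetic core of modern Kernza germplasm. The last line is the masking
validation on a synthetic 50-accession genebank at the pipeline's default
conditions: every masked genet is returned to its true accession.

The same stages are available from a shell:

```sh
iwgtrace run --seed 13 --out-dir demo_run   # simulate → call → filter →
                                            # profile → assign → validate →
                                            # infer-founders, with a manifest
```

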