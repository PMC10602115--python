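"""High-level simulation benchmarks composed from the pipeline stages.

These drive the synthetic generator end to end through calling, filtering and
assignment, and are what the validation benchmarks and the command-line
pipeline share.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_data as sd
from .founders import FounderReport, count_founders
from .genotypes import (
    DosageMatrix,
    call_from_depths,
    filter_genets,
    filter_loci,
    pool_accessions,
)
from .relate import ValidationResult, assign, loo_validate


def observe_and_filter(
    dosages: DosageMatrix,
    mean_depth: float,
    missing_rate: float,
    seed: int,
    locus_subset: set[str] | None = None,
) -> DosageMatrix:
    """GBS-observe true dosages, re-call, and apply the standard filters.

    ``locus_subset`` restricts to loci that survived filtering elsewhere (so
    queries and references stay on a common marker panel).
    """
    depths = sd.simulate_gbs(dosages, mean_depth, missing_rate, seed)
    called = call_from_depths(depths)
    if locus_subset is None:
        called, _ = filter_loci(called)
    else:
        keep = np.array([l in locus_subset for l in called.locus_ids])
        called = called.subset_loci(keep)
    called, _ = filter_genets(called)
    return called


def loo_benchmark(config: sd.SimConfig) -> ValidationResult:
    """Leave-one-out assignment accuracy on one simulated cohort.

    Simulates the configured founder accessions and genets, pushes them
    through the GBS observation layer, depth-gated calling and the standard
    marker/genet filters, then runs the masking validation.
    """
    dosages, membership, _ = sd.simulate_founder_cohort(config)
    called = observe_and_filter(
        dosages, config.mean_depth, config.missing_rate, seed=config.seed + 2
    )
    return loo_validate(called, membership)


def founder_recovery_benchmark(
    config: sd.SimConfig,
    n_true_founders: int = 20,
    parents_per_founder: int = 3,
    k: int = 20,
) -> tuple[FounderReport, set[str], float]:
    """Simulated founder-recovery experiment.

    A random subset of accessions is intermated in a polycross; descendants
    are GBS-observed and assigned back to composite accession profiles built
    from all candidate accessions.  Returns the founder report, the true
    founder set, and the precision of the inferred top-k set.
    """
    dosages, membership, pedigree = sd.simulate_founder_cohort(config)
    rng = np.random.default_rng(config.seed)
    accessions = sorted(set(membership.values()))
    if n_true_founders > len(accessions):
        raise ValueError("more true founders than accessions")
    true = set(rng.choice(accessions, size=n_true_founders, replace=False))

    per_acc: dict[str, int] = {}
    parent_rows = []
    for i, g in enumerate(dosages.genet_ids):
        acc = membership[g]
        if acc in true and per_acc.get(acc, 0) < parents_per_founder:
            per_acc[acc] = per_acc.get(acc, 0) + 1
            parent_rows.append(i)
    parents = dosages.subset_genets(np.isin(np.arange(len(dosages.genet_ids)), parent_rows))
    descendants, _ = sd.simulate_polycross(
        parents, config.n_cycles, config.n_progeny_per_cycle,
        seed=config.seed + 1, parent_pedigree=pedigree,
    )

    references = observe_and_filter(
        dosages, config.mean_depth, config.missing_rate, seed=config.seed + 2
    )
    queries = observe_and_filter(
        descendants, config.mean_depth, config.missing_rate,
        seed=config.seed + 3, locus_subset=set(references.locus_ids),
    )
    profiles = pool_accessions(references, membership)
    assignments = assign(queries, profiles)
    report = count_founders(assignments, k=k)
    precision = len(set(report.top_k_set) & true) / len(report.top_k_set)
    return report, true, precision
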