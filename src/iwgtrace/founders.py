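"""Founder inference from per-genet assignments.

Turns assignment tables into founder evidence: which genebank accessions were
even available to the breeding program (collected before the cutoff year, or
donated), how many modern genets trace to each candidate, the top-k founder
set under the historical head-count constraint, and the overlap between
independently derived founder sets (historical records vs molecular pools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import AccessionProfile, DosageMatrix
from .passport import PassportRecord
from .relate import Assignment, assign

log = logging.getLogger(__name__)


@dataclass
class FounderReport:
    counts: dict[str, int]
    total_queries: int
    top_k_set: list[str]
    top_k_fraction: float
    n_accessions_hit: int
    singletons: list[str]
    singleton_threshold: int
    n_unassigned: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession_id": acc,
                    "n_assigned": n,
                    "in_top_k": acc in set(self.top_k_set),
                    "singleton": acc in set(self.singletons),
                }
                for acc, n in self.counts.items()
            ]
        )


def availability_filter(
    passports: Iterable[PassportRecord], cutoff_year: int = 1990
) -> set[str]:
    """Accessions that could have been obtained by the breeding program.

    Excludes accessions *collected* strictly after the cutoff year; donated
    accessions are exempt and accessions with an unknown year are retained
    (exclusion needs positive evidence) with a logged note.
    """
    available = set()
    for rec in passports:
        if rec.acquisition_mode == "collected" and rec.acquisition_year is not None:
            if rec.acquisition_year > cutoff_year:
                continue
        elif rec.acquisition_year is None and rec.acquisition_mode != "donated":
            log.info(
                "accession %s retained despite unknown acquisition year",
                rec.accession_id,
            )
        available.add(rec.accession_id)
    return available


def count_founders(
    assignments: Sequence[Assignment],
    k: int = 20,
    allowed: set[str] | None = None,
    singleton_threshold: int = 10,
    queries: DosageMatrix | None = None,
    references: Sequence[AccessionProfile] | None = None,
    on_disallowed: str = "reassign",
) -> FounderReport:
    """Tally best-accession assignments into a founder report.

    ``allowed`` restricts the candidate founder pool (availability filter).
    Assignments pointing outside it are re-assigned to the nearest allowed
    accession when ``queries`` and ``references`` are provided (the default,
    mirroring restriction of the candidate pool before assignment), or dropped
    with ``on_disallowed='discard'``.

    ``top_k_set`` holds the min(k, accessions hit) most-assigned accessions,
    ordered by descending count then accession id; accessions tied with the
    k-th count are all included (overflow logged).  ``singletons`` lists
    accessions with at most ``singleton_threshold`` assignments.
    """
    assignments = [a for a in assignments if a.assigned]
    if not assignments:
        raise ValueError("no assigned queries to count")

    if allowed is not None:
        outside = [a for a in assignments if a.best_accession not in allowed]
        if outside:
            if queries is not None and references is not None:
                redo_ids = {a.query_id for a in outside}
                keep_rows = [g in redo_ids for g in queries.genet_ids]
                sub = queries.subset_genets(np.asarray(keep_rows, dtype=bool))
                redone = {a.query_id: a for a in assign(sub, references, allowed=allowed)}
                assignments = [
                    redone.get(a.query_id, a) if a.query_id in redone else a
                    for a in assignments
                ]
                assignments = [a for a in assignments if a.assigned]
            elif on_disallowed == "discard":
                assignments = [a for a in assignments if a.best_accession in allowed]
            else:
                raise ValueError(
                    f"{len(outside)} assignments fall outside the allowed set; "
                    "pass queries+references to re-assign or on_disallowed='discard'"
                )

    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.best_accession] = counts.get(a.best_accession, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = dict(ordered)

    top = ordered[: min(k, len(ordered))]
    if len(ordered) > k:
        kth = top[-1][1]
        extra = [kv for kv in ordered[k:] if kv[1] == kth]
        if extra:
            log.warning(
                "%d accessions tie with the rank-%d count (%d); all included",
                len(extra), k, kth,
            )
            top = top + extra
    top_set = [acc for acc, _ in top]
    total = len(assignments)
    return FounderReport(
        counts=counts,
        total_queries=total,
        top_k_set=top_set,
        top_k_fraction=sum(n for _, n in top) / total,
        n_accessions_hit=len(counts),
        singletons=[acc for acc, n in ordered if n <= singleton_threshold],
        singleton_threshold=singleton_threshold,
    )


@dataclass
class VennResult:
    """All Venn regions for a family of named sets."""

    set_names: list[str]
    exclusive: dict[tuple[str, ...], set[str]] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    union: set[str] = field(default_factory=set)
    common: set[str] = field(default_factory=set)

    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.exclusive.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": "&".join(names),
                    "n": len(members),
                    "members": ";".join(sorted(members)),
                }
                for names, members in self.exclusive.items()
            ]
        )


def intersect_sources(sources: Mapping[str, Iterable[str]]) -> VennResult:
    """Exclusive Venn regions, pairwise intersections, union and common core.

    ``exclusive[(a, b)]`` holds the labels in exactly sets ``a`` and ``b`` and
    no other, so the region cardinalities always sum to the union size.
    """
    sets = {name: set(v) for name, v in sources.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 named sets")
    names = list(sets)
    result = VennResult(set_names=names)
    result.union = set().union(*sets.values())
    result.common = set.intersection(*sets.values())
    for r in range(1, len(names) + 1):
        for group in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in group))
            outside = set().union(*(sets[n] for n in names if n not in group), set())
            result.exclusive[group] = inside - outside
    for a, b in combinations(names, 2):
        result.pairwise[(a, b)] = sets[a] & sets[b]
    return result
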