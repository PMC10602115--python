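"""Pairwise-distance relationship matrix, accession assignment, and the
leave-one-out masking validation.

The metric is Euclidean distance over the loci where both vectors are called,
rescaled by ``sqrt(n_total / n_shared)`` — the convention R's ``dist`` uses for
missing data — so sparser pairs are compared on the same scale as complete
ones.  Queries are assigned to the accession with the smallest distance to its
composite profile; ties break lexicographically on accession id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import AccessionProfile, DosageMatrix, profiles_to_matrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    item_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.item_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape}, expected {(n, n)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.item_ids, columns=self.item_ids)


@dataclass
class Assignment:
    query_id: str
    best_accession: str | None
    best_distance: float
    second_accession: str | None
    second_distance: float
    n_shared_loci_best: int
    tie: bool = False

    @property
    def assigned(self) -> bool:
        return self.best_accession is not None


@dataclass
class ValidationResult:
    n_queries: int
    n_correct: int
    n_skipped_singletons: int = 0
    assignments: list[tuple[str, str, Assignment]] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_queries if self.n_queries else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": q,
                    "true_accession": true,
                    "assigned_accession": a.best_accession,
                    "best_distance": a.best_distance,
                    "second_accession": a.second_accession,
                    "second_distance": a.second_distance,
                    "correct": a.best_accession == true,
                }
                for q, true, a in self.assignments
            ]
        )


def cross_distance(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Missing-scaled Euclidean distances between the rows of two matrices.

    Returns ``(d, shared)`` where ``d[i, j]`` is the distance between
    ``x[i]`` and ``y[j]`` over their shared non-missing loci, rescaled by
    ``sqrt(n_loci / shared)``, and ``shared[i, j]`` counts those loci.
    Pairs with no shared locus get ``NaN``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("locus dimensions differ")
    n_loci = x.shape[1]
    mx = (~np.isnan(x)).astype(float)
    my = (~np.isnan(y)).astype(float)
    x0 = np.nan_to_num(x)
    y0 = np.nan_to_num(y)
    shared = mx @ my.T
    ss = (x0**2 * mx) @ my.T + mx @ (y0**2 * my).T - 2.0 * (x0 @ y0.T)
    ss = np.clip(ss, 0.0, None)  # guard tiny negative round-off
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(n_loci / shared * ss)
    d[shared == 0] = np.nan
    return d, shared.astype(int)


def pairwise_distance(
    rows: np.ndarray | DosageMatrix | Sequence[AccessionProfile],
    item_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Symmetric missing-scaled Euclidean distance matrix over row vectors.

    Accepts a raw array, a :class:`DosageMatrix`, or accession profiles.
    Pairs with no shared locus are set to ``NaN`` with a logged warning.
    """
    if isinstance(rows, DosageMatrix):
        mat, ids = rows.dosage, list(rows.genet_ids)
    elif isinstance(rows, np.ndarray):
        mat = rows
        ids = list(item_ids) if item_ids else [f"item{i}" for i in range(len(rows))]
    else:
        ids, mat = profiles_to_matrix(list(rows))
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    d, shared = cross_distance(mat, mat)
    if (shared == 0).any():
        log.warning("%d pairs share no called locus", int((shared == 0).sum() // 2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry despite float association order
    return DistanceMatrix(ids, d)


def _rank_assignments(
    query_ids: Sequence[str],
    ref_ids: Sequence[str],
    d: np.ndarray,
    shared: np.ndarray,
) -> list[Assignment]:
    """Turn a query x reference distance block into ranked assignments.

    ``ref_ids`` must already be lexicographically sorted so that stable argsort
    breaks distance ties toward the smaller accession id.
    """
    out = []
    d_for_sort = np.where(np.isnan(d), np.inf, d)
    order = np.argsort(d_for_sort, axis=1, kind="stable")
    for i, qid in enumerate(query_ids):
        if np.isinf(d_for_sort[i]).all():
            log.warning("query %s shares no loci with any reference", qid)
            out.append(Assignment(qid, None, np.nan, None, np.nan, 0))
            continue
        b = order[i, 0]
        s = order[i, 1] if d.shape[1] > 1 else None
        tie = s is not None and np.isclose(d[i, b], d_for_sort[i, s])
        if tie:
            log.info("query %s: distance tie between %s and %s", qid, ref_ids[b], ref_ids[s])
        out.append(
            Assignment(
                query_id=qid,
                best_accession=ref_ids[b],
                best_distance=float(d[i, b]),
                second_accession=ref_ids[s] if s is not None else None,
                second_distance=float(d[i, s]) if s is not None and np.isfinite(d_for_sort[i, s]) else float("nan"),
                n_shared_loci_best=int(shared[i, b]),
                tie=bool(tie),
            )
        )
    return out


def assign(
    queries: DosageMatrix,
    references: Sequence[AccessionProfile],
    allowed: set[str] | None = None,
) -> list[Assignment]:
    """Assign each query genet to its closest composite accession profile.

    ``allowed`` restricts the candidate pool before ranking (availability
    filtering); queries sharing no locus with any reference are returned
    unassigned and flagged.
    """
    refs = list(references)
    if allowed is not None:
        refs = [r for r in refs if r.accession_id in allowed]
    if not refs:
        raise ValueError("no reference profiles")
    ref_ids, ref_mat = profiles_to_matrix(refs)
    d, shared = cross_distance(queries.dosage, ref_mat)
    return _rank_assignments(queries.genet_ids, ref_ids, d, shared)


def assign_nearest_genet(
    queries: DosageMatrix,
    reference_genets: DosageMatrix,
    membership: Mapping[str, str],
    allowed: set[str] | None = None,
) -> list[Assignment]:
    """Secondary per-genet mode: rank accessions by min-over-member-genet distance.

    Complements :func:`assign` (composite profiles) with the nearest single
    member genet per accession.
    """
    missing = [g for g in reference_genets.genet_ids if g not in membership]
    if missing:
        raise ValueError(f"{len(missing)} reference genets lack membership")
    acc_ids = sorted(
        {
            membership[g]
            for g in reference_genets.genet_ids
            if allowed is None or membership[g] in allowed
        }
    )
    if not acc_ids:
        raise ValueError("no reference accessions")
    acc_index = {a: k for k, a in enumerate(acc_ids)}
    d_g, shared_g = cross_distance(queries.dosage, reference_genets.dosage)
    nq = queries.shape[0]
    d = np.full((nq, len(acc_ids)), np.nan)
    shared = np.zeros((nq, len(acc_ids)), dtype=int)
    d_fill = np.where(np.isnan(d_g), np.inf, d_g)
    for j, g in enumerate(reference_genets.genet_ids):
        acc = membership[g]
        if acc not in acc_index:
            continue
        k = acc_index[acc]
        better = np.isnan(d[:, k]) | (d_fill[:, j] < d[:, k])
        d[better, k] = d_fill[better, j]
        shared[better, k] = shared_g[better, j]
    d[np.isinf(d)] = np.nan
    return _rank_assignments(queries.genet_ids, acc_ids, d, shared)


def loo_validate(
    pi_genets: DosageMatrix, membership: Mapping[str, str]
) -> ValidationResult:
    """Leave-one-out masking validation of accession assignment.

    Each genet in turn is removed from its accession's composite profile (so
    its own calls cannot leak into the reference) and assigned against all
    composite profiles.  Genets whose accession has no other member are
    skipped as queries and tallied separately.
    """
    genet_ids = pi_genets.genet_ids
    missing = [g for g in genet_ids if g not in membership]
    if missing:
        raise ValueError(f"{len(missing)} genets lack membership")
    acc_ids = sorted({membership[g] for g in genet_ids})
    if len(acc_ids) < 2:
        raise ValueError("leave-one-out validation needs at least 2 accessions")
    acc_index = {a: k for k, a in enumerate(acc_ids)}
    n_acc, (n_genets, n_loci) = len(acc_ids), pi_genets.shape

    called = ~np.isnan(pi_genets.dosage)
    x0 = np.nan_to_num(pi_genets.dosage)
    sums = np.zeros((n_acc, n_loci))
    counts = np.zeros((n_acc, n_loci))
    members: dict[int, list[int]] = {k: [] for k in range(n_acc)}
    for i, g in enumerate(genet_ids):
        k = acc_index[membership[g]]
        members[k].append(i)
        sums[k] += x0[i]
        counts[k] += called[i]

    with np.errstate(invalid="ignore"):
        profiles = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # distances of every genet to every full profile; own-accession column is
    # then recomputed against the leave-one-out profile
    d, shared = cross_distance(pi_genets.dosage, profiles)

    result = ValidationResult(n_queries=0, n_correct=0)
    is_query = np.ones(n_genets, dtype=bool)
    for k, idx in members.items():
        if len(idx) < 2:
            for i in idx:
                is_query[i] = False
            result.n_skipped_singletons += len(idx)
            continue
        idx = np.asarray(idx)
        loo_counts = counts[k] - called[idx]
        loo_sums = sums[k] - x0[idx]
        with np.errstate(invalid="ignore"):
            loo_prof = np.where(loo_counts > 0, loo_sums / np.maximum(loo_counts, 1), np.nan)
        both = called[idx] & ~np.isnan(loo_prof)
        diff = np.where(both, x0[idx] - np.nan_to_num(loo_prof), 0.0)
        sh = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_own = np.sqrt(n_loci / sh * (diff**2).sum(axis=1))
        d_own[sh == 0] = np.nan
        d[idx, k] = d_own
        shared[idx, k] = sh

    queries = np.flatnonzero(is_query)
    ranked = _rank_assignments(
        [genet_ids[i] for i in queries], acc_ids, d[queries], shared[queries]
    )
    for i, a in zip(queries, ranked):
        true_acc = membership[genet_ids[i]]
        result.assignments.append((genet_ids[i], true_acc, a))
        result.n_queries += 1
        if a.best_accession == true_acc:
            result.n_correct += 1
    return result


def write_assignments_tsv(path, assignments: Sequence[Assignment]) -> None:
    pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "best_accession": a.best_accession,
                "best_distance": a.best_distance,
                "second_accession": a.second_accession,
                "second_distance": a.second_distance,
                "n_shared_loci": a.n_shared_loci_best,
                "tie": a.tie,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_assignments_tsv(path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return [
        Assignment(
            query_id=str(r["query_id"]),
            best_accession=None if pd.isna(r["best_accession"]) else str(r["best_accession"]),
            best_distance=float(r["best_distance"]) if pd.notna(r["best_distance"]) else float("nan"),
            second_accession=None if pd.isna(r["second_accession"]) else str(r["second_accession"]),
            second_distance=float(r["second_distance"]) if pd.notna(r["second_distance"]) else float("nan"),
            n_shared_loci_best=int(r["n_shared_loci"]),
            tie=bool(r["tie"]),
        )
        for _, r in df.iterrows()
    ]
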