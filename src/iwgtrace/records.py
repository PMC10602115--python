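"""Historical phenotype computations and reconstruction of the selected subset.

The evaluation traits are the three seed-yield components recorded in the
1988-89 nursery: 100-seed weight (g, mean of three 100-seed samples at 12%
moisture), seed-set rating (SSR, % — clean threshed seed weight over
unthreshed seed-head weight from 10 heads), and seed yield (g) per 10 heads.

Two-year trait summaries average the per-year means (equal year weighting)
rather than pooling all cells, because the historical yield column is only
partially recorded in the drought year and pooling would over-weight the year
with more records.  Reconstruction searches for the k-accession subset whose
combined-year trait means best match recorded target values, exhaustively when
the subset count is small and by greedy construction plus pairwise-swap local
search otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HUNDRED_SEED_WEIGHT = "hundred_seed_weight_g"
SEED_SET_RATING = "seed_set_rating_pct"
YIELD_PER_10_HEADS = "yield_per_10_heads_g"
TRAITS = (HUNDRED_SEED_WEIGHT, SEED_SET_RATING, YIELD_PER_10_HEADS)

PHENOTYPE_COLUMNS = ["accession_id", "trait", "year", "value"]


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype table invariants."""
    if not set(PHENOTYPE_COLUMNS) <= set(table.columns):
        raise ValueError(f"phenotype table needs columns {PHENOTYPE_COLUMNS}")
    if table.duplicated(["accession_id", "trait", "year"]).any():
        raise ValueError("duplicate (accession, trait, year) rows")
    present = table.dropna(subset=["value"])
    bad_ssr = present[
        (present["trait"] == SEED_SET_RATING)
        & ~present["value"].between(0, 100)
    ]
    if len(bad_ssr):
        raise ValueError("seed-set rating outside [0, 100]")
    bad_hsw = present[
        (present["trait"] == HUNDRED_SEED_WEIGHT) & (present["value"] <= 0)
    ]
    if len(bad_hsw):
        raise ValueError("non-positive 100-seed weight")
    bad_yield = present[
        (present["trait"] == YIELD_PER_10_HEADS) & (present["value"] < 0)
    ]
    if len(bad_yield):
        raise ValueError("negative yield")
    return table


def seed_set_rating(clean_seed_g: float, unthreshed_heads_g: float) -> float:
    """Seed-set rating %: clean threshed seed mass over unthreshed head mass."""
    if unthreshed_heads_g <= 0:
        raise ValueError("unthreshed head weight must be positive")
    if clean_seed_g < 0:
        raise ValueError("clean seed weight cannot be negative")
    if clean_seed_g > unthreshed_heads_g:
        raise ValueError("clean seed cannot outweigh the unthreshed heads")
    return 100.0 * clean_seed_g / unthreshed_heads_g


def hundred_seed_weight(samples: Sequence[float]) -> float:
    """Mean mass of exactly three 100-seed samples (dried to 12% moisture)."""
    if len(samples) != 3:
        raise ValueError("exactly three 100-seed samples required")
    if any(s <= 0 for s in samples):
        raise ValueError("sample masses must be positive")
    return float(np.mean(samples))


@dataclass
class TraitSummary:
    means: dict[str, float]
    year_means: dict[str, dict[int, float]]
    missing_cells: list[tuple[str, str, int]] = field(default_factory=list)


def trait_summary(
    table: pd.DataFrame,
    accessions: Sequence[str] | None = None,
    traits: Sequence[str] | None = None,
    year_weighting: str = "equal",
) -> TraitSummary:
    """Combined-year trait means over a set of accessions.

    ``year_weighting='equal'`` (default) averages each year's mean over the
    accessions recorded that year; ``'pooled'`` averages all non-missing cells
    directly.  Missing cells are excluded from their year's mean and reported.
    """
    if year_weighting not in ("equal", "pooled"):
        raise ValueError("year_weighting must be 'equal' or 'pooled'")
    df = table
    if accessions is not None:
        df = df[df["accession_id"].isin(set(accessions))]
    if traits is None:
        traits = sorted(df["trait"].unique())
    summary = TraitSummary(means={}, year_means={})
    for trait in traits:
        sub = df[df["trait"] == trait]
        present = sub.dropna(subset=["value"])
        if present.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        for _, row in sub[sub["value"].isna()].iterrows():
            summary.missing_cells.append(
                (str(row["accession_id"]), trait, int(row["year"]))
            )
        ym = present.groupby("year")["value"].mean()
        summary.year_means[trait] = {int(y): float(v) for y, v in ym.items()}
        if year_weighting == "equal":
            summary.means[trait] = float(ym.mean())
        else:
            summary.means[trait] = float(present["value"].mean())
    return summary


@dataclass
class SubsetSolution:
    chosen: list[str]
    achieved_means: dict[str, float]
    objective: float
    method: str
    n_evaluated: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"accession_id": self.chosen})


class _SubsetObjective:
    """Fast repeated evaluation of the target-matching loss over subsets.

    Precomputes an (n_accessions, n_traits, n_years) value cube so a subset's
    combined-year means reduce to masked sums.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        targets: Mapping[str, float],
        weights: Mapping[str, float] | None,
        year_weighting: str,
    ) -> None:
        for t, v in targets.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"target for {t!r} must be finite and positive")
        self.traits = sorted(targets)
        self.targets = np.array([targets[t] for t in self.traits])
        weights = weights or {}
        self.weights = np.array([weights.get(t, 1.0) for t in self.traits])
        self.year_weighting = year_weighting
        df = table[table["trait"].isin(self.traits)]
        self.accessions = sorted(df["accession_id"].unique())
        self.years = sorted(df["year"].unique())
        acc_i = {a: i for i, a in enumerate(self.accessions)}
        t_i = {t: i for i, t in enumerate(self.traits)}
        y_i = {y: i for i, y in enumerate(self.years)}
        cube = np.full((len(self.accessions), len(self.traits), len(self.years)), np.nan)
        for _, row in df.dropna(subset=["value"]).iterrows():
            cube[acc_i[row["accession_id"]], t_i[row["trait"]], y_i[row["year"]]] = row["value"]
        self.cube = cube
        self.present = ~np.isnan(cube)
        self.cube0 = np.nan_to_num(cube)

    def subset_means(self, idx: np.ndarray) -> np.ndarray:
        counts = self.present[idx].sum(axis=0)  # (traits, years)
        sums = self.cube0[idx].sum(axis=0)
        with np.errstate(invalid="ignore"):
            if self.year_weighting == "equal":
                ym = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
                n_years = (~np.isnan(ym)).sum(axis=1)
                return np.where(
                    n_years > 0, np.nansum(ym, axis=1) / np.maximum(n_years, 1), np.nan
                )
            tot = counts.sum(axis=1)
            return np.where(tot > 0, sums.sum(axis=1) / np.maximum(tot, 1), np.nan)

    def __call__(self, idx: np.ndarray) -> float:
        means = self.subset_means(idx)
        rel = (means - self.targets) / self.targets
        rel = np.where(np.isnan(rel), np.inf, rel)
        return float(np.sum(self.weights * rel**2))


def evaluate_subset(
    table: pd.DataFrame,
    subset: Sequence[str],
    targets: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    year_weighting: str = "equal",
) -> SubsetSolution:
    """Score a fixed accession subset against the trait targets."""
    obj = _SubsetObjective(table, targets, weights, year_weighting)
    missing = set(subset) - set(obj.accessions)
    if missing:
        raise ValueError(f"subset accessions absent from table: {sorted(missing)}")
    idx = np.array([obj.accessions.index(a) for a in subset])
    means = obj.subset_means(idx)
    return SubsetSolution(
        chosen=sorted(subset),
        achieved_means=dict(zip(obj.traits, means.tolist())),
        objective=obj(idx),
        method="fixed",
        n_evaluated=1,
    )


def reconstruct_selection(
    table: pd.DataFrame,
    k: int,
    targets: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    locked: Sequence[str] = (),
    max_exhaustive: int = 1_000_000,
    n_restarts: int = 10,
    seed: int = 0,
    year_weighting: str = "equal",
) -> SubsetSolution:
    """Find the k-accession subset whose trait means best match the targets.

    Minimizes the weighted relative squared deviation
    ``sum_t w_t * ((mean_t(S) - target_t) / target_t)**2``.  When the number of
    candidate subsets is at most ``max_exhaustive`` the search is exhaustive;
    otherwise a greedy build-up is refined by pairwise-swap local search with
    seeded random restarts.  ``locked`` accessions are always included.
    """
    obj = _SubsetObjective(table, targets, weights, year_weighting)
    n = len(obj.accessions)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} candidate accessions")
    locked = sorted(set(locked))
    bad_locks = set(locked) - set(obj.accessions)
    if bad_locks or len(locked) > k:
        raise ValueError(f"infeasible locked set: {sorted(bad_locks) or locked}")
    locked_idx = [obj.accessions.index(a) for a in locked]
    free = [i for i in range(n) if i not in set(locked_idx)]
    n_choose = k - len(locked_idx)

    def finish(idx, objective, method, n_eval):
        return SubsetSolution(
            chosen=sorted(obj.accessions[i] for i in idx),
            achieved_means=dict(zip(obj.traits, obj.subset_means(np.asarray(idx)).tolist())),
            objective=objective,
            method=method,
            n_evaluated=n_eval,
            seed=seed,
        )

    if comb(len(free), n_choose) <= max_exhaustive:
        best, best_obj, n_eval = None, np.inf, 0
        for chosen in combinations(free, n_choose):
            idx = np.array(locked_idx + list(chosen))
            v = obj(idx)
            n_eval += 1
            if v < best_obj:
                best, best_obj = idx, v
        return finish(best, best_obj, "exhaustive", n_eval)

    rng = np.random.default_rng(seed)
    best, best_obj, n_eval = None, np.inf, 0

    def local_search(idx_set: set[int]):
        # best-improvement pairwise swaps until a local optimum
        nonlocal n_eval
        current = set(idx_set)
        cur_obj = obj(np.array(sorted(current)))
        n_eval += 1
        while True:
            best_swap, best_v = None, cur_obj
            for out in sorted(current - set(locked_idx)):
                for inn in free:
                    if inn in current:
                        continue
                    v = obj(np.array(sorted((current - {out}) | {inn})))
                    n_eval += 1
                    if v < best_v - 1e-12:
                        best_swap, best_v = (out, inn), v
            if best_swap is None:
                return current, cur_obj
            current = (current - {best_swap[0]}) | {best_swap[1]}
            cur_obj = best_v

    for restart in range(max(1, n_restarts)):
        if restart == 0:
            # greedy build-up from the locked core
            current = set(locked_idx)
            while len(current) < k:
                best_add, best_v = None, np.inf
                for i in free:
                    if i in current:
                        continue
                    v = obj(np.array(sorted(current | {i})))
                    n_eval += 1
                    if best_add is None or v < best_v:
                        best_add, best_v = i, v
                current.add(best_add)
        else:
            pick = rng.choice(free, size=n_choose, replace=False)
            current = set(locked_idx) | set(int(i) for i in pick)
        current, cur_obj = local_search(current)
        if cur_obj < best_obj:
            best, best_obj = sorted(current), cur_obj
    return finish(best, best_obj, "greedy+swap", n_eval)
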