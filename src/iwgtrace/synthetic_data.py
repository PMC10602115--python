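"""Synthetic polycross / GBS data generator.

Emulates the structure the founder-inference analysis assumes: hierarchically
diverged founder accessions (Balding-Nichols Beta model around a shared
ancestral frequency), a handful of Hardy-Weinberg genets per accession, open
polycross intermating over one or more cycles (random distinct parent pairs,
one Mendelian gamete each, no selfing, no linkage), a GBS observation layer
with Poisson read depth and dropout, and two-year phenotype records with
genotype-by-environment interaction.

Defaults mirror the study conditions the downstream benchmarks use: 50
accessions of 6 genets at 2,000 loci with Fst 0.15, mean read depth 8 with 30%
dropout, and 2 polycross cycles of 300 progeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import DepthMatrix, DosageMatrix
from .passport import PassportRecord


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimConfig:
    n_accessions: int = 50
    n_genets_per_accession: int = 6
    n_loci: int = 2000
    fst: float = 0.15
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 8.0
    missing_rate: float = 0.30
    n_cycles: int = 2
    n_progeny_per_cycle: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_genets_per_accession", "n_loci",
                     "n_cycles", "n_progeny_per_cycle"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
            setattr(self, name, int(getattr(self, name)))
        if not (0.0 < self.fst < 1.0):
            raise ConfigError("fst must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range must lie within (0, 0.5]")
        if self.mean_depth < 0:
            raise ConfigError("mean_depth must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "ancestral_maf_range" in kwargs and not isinstance(
            kwargs["ancestral_maf_range"], tuple
        ):
            kwargs["ancestral_maf_range"] = tuple(kwargs["ancestral_maf_range"])
        return cls(**kwargs)


@dataclass
class FounderAccession:
    accession_id: str
    allele_freqs: np.ndarray
    passport: PassportRecord

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if ((self.allele_freqs < 0) | (self.allele_freqs > 1)).any():
            raise ConfigError("allele frequencies must lie in [0, 1]")


@dataclass
class PedigreeRecord:
    genet_id: str
    generation: int
    parent_ids: tuple[str, ...] = ()
    source_accession: str | None = None

    def __post_init__(self) -> None:
        if self.generation == 0 and self.parent_ids:
            raise ConfigError("founder genets have no parents")
        if self.generation > 0 and len(self.parent_ids) != 2:
            raise ConfigError("non-founder genets need exactly two parents")


_COUNTRIES = ["Russia", "Kazakhstan", "Turkey", "Iran", "Uzbekistan", "Afghanistan"]


def _synthetic_passport(acc_id: str, idx: int, rng: np.random.Generator) -> PassportRecord:
    """Plausible synthetic passport: wild collections from the 1960s-80s."""
    return PassportRecord(
        accession_id=acc_id,
        pi_number=f"{900000 + idx}",
        origin_country=_COUNTRIES[idx % len(_COUNTRIES)],
        status="wild",
        acquisition_mode="collected",
        acquisition_year=int(rng.integers(1960, 1986)),
    )


def simulate_founders(config: SimConfig) -> list[FounderAccession]:
    """Draw founder accession allele frequencies under the Balding-Nichols model.

    A shared ancestral minor-allele frequency is drawn uniformly per locus from
    ``ancestral_maf_range`` and unfolded to a random allele orientation; each
    accession's frequency is then Beta-distributed with mean p and variance
    ``fst * p * (1 - p)``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=config.n_loci)
    flip = rng.random(config.n_loci) < 0.5
    p = np.where(flip, 1.0 - maf, maf)
    ratio = (1.0 - config.fst) / config.fst
    a, b = p * ratio, (1.0 - p) * ratio
    width = len(str(config.n_accessions))
    founders = []
    for i in range(config.n_accessions):
        q = rng.beta(a, b)
        acc_id = f"ACC{i + 1:0{width}d}"
        founders.append(
            FounderAccession(acc_id, q, _synthetic_passport(acc_id, i, rng))
        )
    return founders


def simulate_genets(
    accession: FounderAccession,
    n: int,
    seed: int,
    locus_ids: Sequence[str] | None = None,
) -> tuple[DosageMatrix, list[PedigreeRecord]]:
    """Draw ``n`` Hardy-Weinberg genets: dosage ~ Binomial(2, q) per locus."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    q = accession.allele_freqs
    dosage = rng.binomial(2, q, size=(n, q.size)).astype(float)
    genet_ids = [f"{accession.accession_id}_g{i + 1}" for i in range(n)]
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(q.size)]
    pedigree = [
        PedigreeRecord(g, 0, (), accession.accession_id) for g in genet_ids
    ]
    return DosageMatrix(genet_ids, list(locus_ids), dosage), pedigree


def simulate_founder_cohort(
    config: SimConfig, founders: Sequence[FounderAccession] | None = None
) -> tuple[DosageMatrix, dict[str, str], list[PedigreeRecord]]:
    """All founder genets stacked into one matrix, with membership and pedigree."""
    if founders is None:
        founders = simulate_founders(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(founders))
    locus_ids = [f"L{j + 1}" for j in range(config.n_loci)]
    mats, membership, pedigree = [], {}, []
    for acc, ss in zip(founders, seeds):
        m, ped = simulate_genets(
            acc, config.n_genets_per_accession, ss, locus_ids=locus_ids
        )
        mats.append(m)
        pedigree.extend(ped)
        for g in m.genet_ids:
            membership[g] = acc.accession_id
    dosage = np.vstack([m.dosage for m in mats])
    genet_ids = [g for m in mats for g in m.genet_ids]
    return DosageMatrix(genet_ids, locus_ids, dosage), membership, pedigree


def simulate_polycross(
    parents: DosageMatrix,
    cycles: int,
    n_progeny: int,
    seed: int,
    parent_pedigree: Iterable[PedigreeRecord] = (),
) -> tuple[DosageMatrix, list[PedigreeRecord]]:
    """Random intermating without selfing for ``cycles`` generations.

    Each progeny draws two distinct parents uniformly at random and one
    Mendelian gamete per parent per locus; loci segregate independently.  After
    each cycle the progeny replace the parent pool.  Returns the final cycle's
    progeny and the pedigree of every intermediate generation.
    """
    if parents.shape[0] < 2:
        raise ConfigError("polycross requires at least 2 parents")
    if np.isnan(parents.dosage).any():
        raise ConfigError("parent dosages must be complete (no missing)")
    if cycles < 1 or n_progeny < 1:
        raise ConfigError("cycles and n_progeny must be >= 1")
    rng = np.random.default_rng(seed)
    gen0 = max((p.generation for p in parent_pedigree), default=0)
    pool = parents
    pedigree: list[PedigreeRecord] = []
    for c in range(1, cycles + 1):
        n_par = pool.shape[0]
        i1 = rng.integers(n_par, size=n_progeny)
        i2 = (i1 + 1 + rng.integers(n_par - 1, size=n_progeny)) % n_par
        with np.errstate(invalid="ignore"):
            g1 = rng.binomial(1, pool.dosage[i1] / 2.0)
            g2 = rng.binomial(1, pool.dosage[i2] / 2.0)
        dosage = (g1 + g2).astype(float)
        gen = gen0 + c
        ids = [f"SYN{gen}_p{k + 1}" for k in range(n_progeny)]
        for k, gid in enumerate(ids):
            pedigree.append(
                PedigreeRecord(
                    gid, gen, (pool.genet_ids[i1[k]], pool.genet_ids[i2[k]]), None
                )
            )
        pool = DosageMatrix(ids, list(parents.locus_ids), dosage)
    return pool, pedigree


def simulate_gbs(
    dosages: DosageMatrix,
    mean_depth: float,
    missing_rate: float,
    seed: int,
) -> DepthMatrix:
    """GBS observation layer: Poisson total depth with dropout, binomial alt reads.

    Depth per genet-locus is Poisson(``mean_depth``) zeroed with probability
    ``missing_rate``; alt reads are Binomial(depth, dosage / 2).
    """
    if mean_depth < 0:
        raise ConfigError("mean_depth must be non-negative")
    if not (0.0 <= missing_rate <= 1.0):
        raise ConfigError("missing_rate must lie in [0, 1]")
    if np.isnan(dosages.dosage).any():
        raise ConfigError("true dosages must be complete before GBS observation")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=dosages.shape)
    depth[rng.random(dosages.shape) < missing_rate] = 0
    alt = rng.binomial(depth, dosages.dosage / 2.0)
    return DepthMatrix(
        list(dosages.genet_ids), list(dosages.locus_ids), depth - alt, alt
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeEffectConfig:
    """Variance components for accession x year phenotype simulation.

    ``trait_means`` maps trait name to its overall mean; the four standard
    deviations control the accession main effect, year main effect, the
    accession-by-year interaction (genotype-by-environment), and residual
    noise.  ``missing`` maps (trait, year) to either a fraction of accessions
    to blank at random or an explicit list of accession ids to blank, which
    lets a fixture mimic historical records where one year's trait column was
    only partially recorded.
    """

    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "hundred_seed_weight_g": 0.5,
            "seed_set_rating_pct": 45.0,
            "yield_per_10_heads_g": 2.5,
        }
    )
    sd_accession: float = 1.0
    sd_year: float = 0.5
    sd_interaction: float = 0.5
    sd_noise: float = 0.2
    missing: dict[tuple[str, int], float | list[str]] = field(default_factory=dict)


def simulate_phenotypes(
    accessions: Sequence[str],
    traits: Sequence[str],
    years: Sequence[int],
    effect_config: PhenotypeEffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format phenotype table with G-by-E structure.

    value = trait mean + accession effect + year effect + interaction + noise,
    all effects trait-specific and scaled relative to the trait mean (so a
    0.5 g trait and a 45% trait get comparable relative spread).
    """
    if len(traits) < 1:
        raise ConfigError("at least one trait required")
    if len(years) < 2:
        raise ConfigError("at least two years required")
    cfg = effect_config or PhenotypeEffectConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        mean = cfg.trait_means.get(trait, 1.0)
        scale = abs(mean) / 10.0 or 1.0
        a = rng.normal(0, cfg.sd_accession * scale, size=len(accessions))
        y = rng.normal(0, cfg.sd_year * scale, size=len(years))
        ab = rng.normal(0, cfg.sd_interaction * scale, size=(len(accessions), len(years)))
        e = rng.normal(0, cfg.sd_noise * scale, size=(len(accessions), len(years)))
        for i, acc in enumerate(accessions):
            for j, year in enumerate(years):
                rows.append(
                    {
                        "accession_id": acc,
                        "trait": trait,
                        "year": int(year),
                        "value": mean + a[i] + y[j] + ab[i, j] + e[i, j],
                    }
                )
    df = pd.DataFrame(rows)
    for (trait, year), spec in cfg.missing.items():
        mask = (df["trait"] == trait) & (df["year"] == year)
        if isinstance(spec, (int, float)) and not isinstance(spec, bool):
            ids = df.loc[mask, "accession_id"].unique()
            n_blank = int(round(float(spec) * len(ids)))
            blank = set(rng.choice(ids, size=n_blank, replace=False))
        else:
            blank = set(spec)
        df.loc[mask & df["accession_id"].isin(blank), "value"] = np.nan
    return df


# ---------------------------------------------------------------------------
# artifact writers


def write_pedigree_tsv(path: str | Path, pedigree: Iterable[PedigreeRecord]) -> None:
    rows = [
        {
            "genet_id": p.genet_id,
            "generation": p.generation,
            "parent1": p.parent_ids[0] if p.parent_ids else "NA",
            "parent2": p.parent_ids[1] if p.parent_ids else "NA",
            "source_accession": p.source_accession or "NA",
        }
        for p in pedigree
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["year"] = df["year"].astype(int)
    return df
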