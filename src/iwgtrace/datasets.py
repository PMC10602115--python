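"""Packaged historical fixtures: the Polycross-1 evaluation tables.

Three small TSVs transcribe the published record of the 1980s Rodale
Institute intermediate-wheatgrass program:

* ``table1`` — the 20 accessions inferred from historical documents to be the
  Polycross-1 parents, with their 1988/1989 seed-yield evaluations and
  genebank passport columns.  The ``molecular`` flag marks the six PI
  accessions that were also identified in *all* molecular data sources.
* ``table2`` — 14 further PI accessions implicated only by molecular data.
  Its yield column was recorded for a single season and is stored under 1989.
* ``table3`` — 10 PI accessions from the expanded genebank-wide search that
  the original program never evaluated (passport columns only).

Phenotype loaders return the long (accession, trait, year, value) format used
throughout :mod:`iwgtrace.records`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .passport import PassportRecord
from .records import (
    HUNDRED_SEED_WEIGHT,
    SEED_SET_RATING,
    YIELD_PER_10_HEADS,
    validate_phenotypes,
)

_TRAIT_COLS = {
    HUNDRED_SEED_WEIGHT: "hsw",
    SEED_SET_RATING: "ssr",
    YIELD_PER_10_HEADS: "yield",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("iwgtrace.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"], dtype={"pi_number": str})


def load_table1() -> pd.DataFrame:
    return _read("table1_polycross1_historical.tsv")


def load_table2() -> pd.DataFrame:
    return _read("table2_polycross1_molecular.tsv")


def load_table3() -> pd.DataFrame:
    return _read("table3_expanded_search.tsv")


def _phenotypes(df: pd.DataFrame, years: dict[str, int]) -> pd.DataFrame:
    rows = []
    for _, r in df.iterrows():
        for trait, stem in _TRAIT_COLS.items():
            for col, year in years.items():
                full = f"{stem}_{col}"
                if full not in df.columns:
                    continue
                rows.append(
                    {
                        "accession_id": r["accession_id"],
                        "trait": trait,
                        "year": year,
                        "value": r[full] if pd.notna(r[full]) else np.nan,
                    }
                )
    return validate_phenotypes(pd.DataFrame(rows))


def table1_phenotypes() -> pd.DataFrame:
    """Long-format 1988/1989 trait records for the 20 historical selections."""
    return _phenotypes(load_table1(), {"1988": 1988, "1989": 1989})


def table2_phenotypes() -> pd.DataFrame:
    return _phenotypes(load_table2(), {"1988": 1988, "1989": 1989})


def _passports(df: pd.DataFrame) -> list[PassportRecord]:
    records = []
    for _, r in df.iterrows():
        def opt(col, cast=str):
            return cast(r[col]) if col in df.columns and pd.notna(r[col]) else None

        records.append(
            PassportRecord(
                accession_id=str(r["accession_id"]),
                pi_number=opt("pi_number"),
                origin_country=opt("origin_country"),
                collection_site=opt("collection_site"),
                elevation_m=opt("elevation_m", float),
                status=opt("status") or "unknown",
                cultivar_name=opt("cultivar_name"),
                site_is_garden=bool(r.get("site_is_garden", 0)),
            )
        )
    return records


def table1_passports() -> list[PassportRecord]:
    return _passports(load_table1())


def table2_passports() -> list[PassportRecord]:
    return _passports(load_table2())


def table3_passports() -> list[PassportRecord]:
    return _passports(load_table3())


def polycross1_source_sets() -> dict[str, set[str]]:
    """Named founder-candidate sets for cross-source intersection.

    ``historical``: PI accessions in the reconstructed 20-parent selection;
    ``molecular``: PI accessions implicated by molecular assignment — the
    molecular-only table plus the historically selected PIs confirmed in all
    molecular pools.
    """
    t1 = load_table1()
    historical = set(t1.loc[t1["pi_number"].notna(), "accession_id"])
    bold = set(t1.loc[t1["molecular"] == 1, "accession_id"])
    molecular = set(load_table2()["accession_id"]) | bold
    return {"historical": historical, "molecular": molecular}
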