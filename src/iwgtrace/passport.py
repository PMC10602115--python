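"""Accession passport metadata and geographic-origin summaries.

Genebank passport records carry an accession's declared country of origin,
collection site, elevation, cultivation status, and how and when it entered the
collection.  Origin summaries only count records whose location is judged
reliable: the record must name a present-day country (labels like "Former USSR"
are too coarse) and the collection site must not be a garden or institute —
a botanical-garden sample says where the seed was held, not where the plant
grew wild.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_STATUS = {"wild", "uncertain", "cultivated", "breeding_material", "unknown"}
VALID_ACQUISITION = {"collected", "donated", "unknown"}

#: origin labels that name a defunct polity rather than a present-day state
NON_SPECIFIC_ORIGINS = {"Former USSR", "Former Soviet Union", "USSR", "Soviet Union"}

GARDEN_KEYWORDS = ("botanical garden", "botanic garden", "institute")


@dataclass
class PassportRecord:
    """One accession's genebank passport entry."""

    accession_id: str
    pi_number: str | None = None
    origin_country: str | None = None
    collection_site: str | None = None
    elevation_m: float | None = None
    status: str = "unknown"
    cultivar_name: str | None = None
    acquisition_mode: str = "unknown"
    acquisition_year: int | None = None
    site_is_garden: bool = False

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise ValueError(f"invalid status {self.status!r}")
        if self.acquisition_mode not in VALID_ACQUISITION:
            raise ValueError(f"invalid acquisition_mode {self.acquisition_mode!r}")
        if self.elevation_m is not None and not (-500 <= self.elevation_m <= 6000):
            raise ValueError(f"implausible elevation {self.elevation_m} m")
        if self.collection_site and any(
            kw in self.collection_site.lower() for kw in GARDEN_KEYWORDS
        ):
            self.site_is_garden = True

    @property
    def location_reliable(self) -> bool:
        """True when the record supports a country-of-origin claim."""
        return (
            self.origin_country is not None
            and self.origin_country not in NON_SPECIFIC_ORIGINS
            and not self.site_is_garden
        )


@dataclass
class OriginSummary:
    counts: dict[str, int] = field(default_factory=dict)
    unreliable: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unreliable


def _select(
    records: Iterable[PassportRecord], accessions: Sequence[str] | None
) -> tuple[list[PassportRecord], int]:
    """Restrict records to the requested accessions; count missing records."""
    records = list(records)
    if accessions is None:
        return records, 0
    by_id = {r.accession_id: r for r in records}
    found = [by_id[a] for a in accessions if a in by_id]
    return found, len(set(accessions)) - len(found)


def origin_summary(
    records: Iterable[PassportRecord], accessions: Sequence[str] | None = None
) -> OriginSummary:
    """Country-of-origin counts over location-reliable records.

    Records that are unreliable (no country, defunct-polity label, or garden
    site) and accessions with no passport record at all are tallied under
    ``unreliable`` so that counts always sum to the size of the requested set.
    """
    selected, n_missing = _select(records, accessions)
    summary = OriginSummary(unreliable=n_missing)
    for rec in selected:
        if rec.location_reliable:
            summary.counts[rec.origin_country] = summary.counts.get(rec.origin_country, 0) + 1
        else:
            summary.unreliable += 1
    summary.counts = dict(sorted(summary.counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return summary


def status_summary(
    records: Iterable[PassportRecord], accessions: Sequence[str] | None = None
) -> dict[str, int]:
    """Counts per cultivation-status category; absent records count as unknown."""
    selected, n_missing = _select(records, accessions)
    counts: dict[str, int] = {}
    for rec in selected:
        counts[rec.status] = counts.get(rec.status, 0) + 1
    if n_missing:
        counts["unknown"] = counts.get("unknown", 0) + n_missing
    return dict(sorted(counts.items()))


def pi_sourced_count(
    records: Iterable[PassportRecord], accessions: Sequence[str] | None = None
) -> int:
    """Number of accessions carrying a plant-introduction (PI) number."""
    selected, _ = _select(records, accessions)
    return sum(1 for r in selected if r.pi_number is not None)


# ---------------------------------------------------------------------------
# TSV I/O

_COLUMNS = [
    "accession_id",
    "pi_number",
    "origin_country",
    "collection_site",
    "elevation_m",
    "status",
    "cultivar_name",
    "acquisition_mode",
    "acquisition_year",
    "site_is_garden",
]


def read_passport_tsv(path: str | Path) -> list[PassportRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"pi_number": str})
    records = []
    for _, row in df.iterrows():
        def opt(col, cast=str):
            return cast(row[col]) if col in row and pd.notna(row.get(col)) else None

        records.append(
            PassportRecord(
                accession_id=str(row["accession_id"]),
                pi_number=opt("pi_number"),
                origin_country=opt("origin_country"),
                collection_site=opt("collection_site"),
                elevation_m=opt("elevation_m", float),
                status=opt("status") or "unknown",
                cultivar_name=opt("cultivar_name"),
                acquisition_mode=opt("acquisition_mode") or "unknown",
                acquisition_year=opt("acquisition_year", lambda v: int(float(v))),
                site_is_garden=bool(int(row["site_is_garden"]))
                if pd.notna(row.get("site_is_garden"))
                else False,
            )
        )
    return records


def write_passport_tsv(path: str | Path, records: Iterable[PassportRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "accession_id": r.accession_id,
                "pi_number": r.pi_number,
                "origin_country": r.origin_country,
                "collection_site": r.collection_site,
                "elevation_m": r.elevation_m,
                "status": r.status,
                "cultivar_name": r.cultivar_name,
                "acquisition_mode": r.acquisition_mode,
                "acquisition_year": r.acquisition_year,
                "site_is_garden": int(r.site_is_garden),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False, na_rep="NA")
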