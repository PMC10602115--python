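"""Genotype containers, depth-gated calling, marker/genet filtering, and accession pooling.

The data model is deliberately diploid: intermediate wheatgrass is allohexaploid,
but GBS SNPs here are biallelic diploid-style calls, so genotypes are alt-allele
dosages in {0, 1, 2} with ``NaN`` marking missing.  Calling from raw read depths
follows depth-gating rules: a homozygote requires at least four reads of a single
allele, a heterozygote requires at least one read of each allele, and anything
else is set to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: minimum identical reads to call a homozygote
HOM_MIN_DEPTH = 4
#: minimum reads of *each* allele to call a heterozygote
HET_MIN_CONTRASTING = 1


class DataError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate {what} labels")


@dataclass
class DepthMatrix:
    """Per genet-locus read counts for the reference and alternate allele."""

    genet_ids: list[str]
    locus_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.genet_ids), len(self.locus_ids))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise DataError(
                f"depth matrix shape mismatch: ref {self.ref.shape}, alt "
                f"{self.alt.shape}, expected {shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise DataError("negative read counts")
        _check_unique(self.genet_ids, "genet")
        _check_unique(self.locus_ids, "locus")

    @property
    def total(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genet_ids), len(self.locus_ids))


@dataclass
class DosageMatrix:
    """Genets x loci alt-allele dosages in {0, 1, 2}, ``NaN`` for missing."""

    genet_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        shape = (len(self.genet_ids), len(self.locus_ids))
        if self.dosage.shape != shape:
            raise DataError(
                f"dosage matrix shape {self.dosage.shape}, expected {shape}"
            )
        called = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        _check_unique(self.genet_ids, "genet")
        _check_unique(self.locus_ids, "locus")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genet_ids), len(self.locus_ids))

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-genet fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=1)

    def subset_loci(self, keep: np.ndarray) -> "DosageMatrix":
        ids = [l for l, k in zip(self.locus_ids, keep) if k]
        return DosageMatrix(list(self.genet_ids), ids, self.dosage[:, keep])

    def subset_genets(self, keep: np.ndarray) -> "DosageMatrix":
        ids = [g for g, k in zip(self.genet_ids, keep) if k]
        return DosageMatrix(ids, list(self.locus_ids), self.dosage[keep, :])


@dataclass
class FilterReport:
    """Audit trail of a filtering pass."""

    n_loci_in: int
    n_loci_out: int
    n_genets_in: int
    n_genets_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("loci_in", self.n_loci_in),
            ("loci_out", self.n_loci_out),
            ("genets_in", self.n_genets_in),
            ("genets_out", self.n_genets_out),
        ] + [(f"removed_{rule}", n) for rule, n in self.removed.items()]
        return pd.DataFrame(rows, columns=["quantity", "count"])


@dataclass
class AccessionProfile:
    """Composite genomic profile of one accession.

    ``mean_dosage`` is the per-locus mean alt-allele dosage over the accession's
    member genets with a call at that locus; loci with no called member are
    missing.
    """

    accession_id: str
    mean_dosage: np.ndarray
    n_genets: int

    def __post_init__(self) -> None:
        self.mean_dosage = np.asarray(self.mean_dosage, dtype=float)
        if self.n_genets < 1:
            raise DataError("profile requires at least one genet")
        called = self.mean_dosage[~np.isnan(self.mean_dosage)]
        if ((called < 0) | (called > 2)).any():
            raise DataError("mean dosage outside [0, 2]")


# ---------------------------------------------------------------------------
# calling and filtering


def call_from_depths(depths: DepthMatrix) -> DosageMatrix:
    """Call diploid dosages from allele read depths.

    A cell with at least one read of each allele is a heterozygote (dosage 1);
    a cell where only one allele was observed needs >= 4 reads to be called
    homozygous (0 for ref, 2 for alt); everything else is missing.
    """
    ref, alt = depths.ref, depths.alt
    dosage = np.full(ref.shape, np.nan)
    het = (ref >= HET_MIN_CONTRASTING) & (alt >= HET_MIN_CONTRASTING)
    dosage[het] = 1.0
    dosage[(alt == 0) & (ref >= HOM_MIN_DEPTH)] = 0.0
    dosage[(ref == 0) & (alt >= HOM_MIN_DEPTH)] = 2.0
    return DosageMatrix(list(depths.genet_ids), list(depths.locus_ids), dosage)


def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """Folded minor-allele frequency per locus over non-missing calls.

    Loci with no calls get MAF 0 (they always fail a strict ``> maf_min`` test).
    """
    called = ~np.isnan(dosage)
    n_alleles = 2 * called.sum(axis=0)
    alt_count = np.nansum(dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(f, 1.0 - f)


def filter_loci(
    dosages: DosageMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.30,
    biallelic: np.ndarray | None = None,
) -> tuple[DosageMatrix, FilterReport]:
    """Keep biallelic loci with folded MAF strictly above ``maf_min`` and a
    call rate of at least ``call_rate_min``.

    Removal tallies attribute each dropped locus to the first failing rule, in
    the order non-biallelic, call rate, MAF.
    """
    if not (0 <= maf_min <= 1) or not (0 <= call_rate_min <= 1):
        raise ValueError("maf_min and call_rate_min must lie in [0, 1]")
    n_genets, n_loci = dosages.shape
    if n_loci == 0 or n_genets == 0:
        raise DataError("empty dosage matrix")
    if biallelic is None:
        biallelic = np.ones(n_loci, dtype=bool)
    biallelic = np.asarray(biallelic, dtype=bool)
    if biallelic.shape != (n_loci,):
        raise DataError("biallelic flag length mismatch")

    call_rate = (~np.isnan(dosages.dosage)).mean(axis=0)
    maf = minor_allele_frequency(dosages.dosage)

    fail_bi = ~biallelic
    fail_cr = biallelic & (call_rate < call_rate_min)
    fail_maf = biallelic & ~fail_cr & (maf <= maf_min)
    keep = ~(fail_bi | fail_cr | fail_maf)

    report = FilterReport(
        n_loci_in=n_loci,
        n_loci_out=int(keep.sum()),
        n_genets_in=n_genets,
        n_genets_out=n_genets,
        removed={
            "non_biallelic": int(fail_bi.sum()),
            "call_rate": int(fail_cr.sum()),
            "maf": int(fail_maf.sum()),
        },
    )
    return dosages.subset_loci(keep), report


def filter_genets(
    dosages: DosageMatrix, max_missing: float = 0.95
) -> tuple[DosageMatrix, FilterReport]:
    """Remove genets whose missing fraction strictly exceeds ``max_missing``."""
    if not (0 < max_missing <= 1):
        raise ValueError("max_missing must lie in (0, 1]")
    miss = dosages.missing_fraction
    keep = miss <= max_missing
    report = FilterReport(
        n_loci_in=dosages.shape[1],
        n_loci_out=dosages.shape[1],
        n_genets_in=dosages.shape[0],
        n_genets_out=int(keep.sum()),
        removed={"genet_missingness": int((~keep).sum())},
    )
    return dosages.subset_genets(keep), report


def pool_accessions(
    dosages: DosageMatrix, membership: Mapping[str, str]
) -> list[AccessionProfile]:
    """Build composite accession profiles by averaging member-genet dosages.

    Every genet in ``dosages`` must appear in ``membership``.  Profiles are
    returned sorted by accession id.
    """
    missing = [g for g in dosages.genet_ids if g not in membership]
    if missing:
        raise DataError(
            f"{len(missing)} genets lack accession membership "
            f"(first: {missing[0]!r})"
        )
    by_acc: dict[str, list[int]] = {}
    for i, g in enumerate(dosages.genet_ids):
        by_acc.setdefault(membership[g], []).append(i)
    profiles = []
    for acc in sorted(by_acc):
        rows = dosages.dosage[by_acc[acc], :]
        count = (~np.isnan(rows)).sum(axis=0)
        total = np.nansum(rows, axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        profiles.append(AccessionProfile(acc, mean, len(by_acc[acc])))
    return profiles


def profiles_to_matrix(
    profiles: Sequence[AccessionProfile],
) -> tuple[list[str], np.ndarray]:
    """Stack profiles (sorted by accession id) into an (n_acc, n_loci) array."""
    ordered = sorted(profiles, key=lambda p: p.accession_id)
    ids = [p.accession_id for p in ordered]
    return ids, np.vstack([p.mean_dosage for p in ordered])


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str | Path) -> tuple[DepthMatrix | None, DosageMatrix, np.ndarray]:
    """Read GT (and AD, when present) from a VCF.

    Returns ``(depths, dosages, biallelic)``.  Multi-allelic records are kept
    and flagged non-biallelic so that :func:`filter_loci` can drop them with an
    audit entry; ``depths`` is ``None`` when the file carries no AD field.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    genet_ids = list(vcf.samples)
    locus_ids: list[str] = []
    dosage_rows: list[np.ndarray] = []
    ref_rows: list[np.ndarray] = []
    alt_rows: list[np.ndarray] = []
    biallelic: list[bool] = []
    any_ad = False
    for i, v in enumerate(vcf):
        locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        biallelic.append(len(v.ALT) == 1)
        gt = np.asarray(v.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        row = np.full(len(genet_ids), np.nan)
        row[gt == 0] = 0.0
        row[gt == 1] = 1.0
        row[gt == 3] = 2.0
        dosage_rows.append(row)
        try:
            ad = v.format("AD")
        except KeyError:  # AD absent from the header entirely
            ad = None
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # '.' entries decode as negative sentinels
            ref_rows.append(ad[:, 0])
            alt_rows.append(ad[:, 1:].sum(axis=1))
        else:
            ref_rows.append(np.zeros(len(genet_ids), dtype=np.int64))
            alt_rows.append(np.zeros(len(genet_ids), dtype=np.int64))
    if not locus_ids:
        raise DataError(f"no records in VCF {path}")
    dosages = DosageMatrix(genet_ids, locus_ids, np.column_stack(dosage_rows))
    depths = None
    if any_ad:
        depths = DepthMatrix(
            genet_ids, list(locus_ids), np.column_stack(ref_rows), np.column_stack(alt_rows)
        )
    return depths, dosages, np.asarray(biallelic, dtype=bool)


def write_vcf(
    path: str | Path,
    dosages: DosageMatrix,
    depths: DepthMatrix | None = None,
) -> None:
    """Write dosages (and optional allele depths) as a biallelic VCF 4.2 file.

    One sample per genet; genotypes are unphased GT, depths go into AD.
    Placeholder REF/ALT alleles (A/C) are used — marker identity lives in the
    locus id.
    """
    if depths is not None and (
        depths.genet_ids != dosages.genet_ids or depths.locus_ids != dosages.locus_ids
    ):
        raise DataError("depth and dosage matrices are not aligned")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    fmt = "GT:AD" if depths is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref, alt)">\n'
            )
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.genet_ids)
            + "\n"
        )
        for j, locus in enumerate(dosages.locus_ids):
            cells = []
            for i in range(len(dosages.genet_ids)):
                d = dosages.dosage[i, j]
                gt = "./." if np.isnan(d) else gt_map[d]
                if depths is not None:
                    cells.append(f"{gt}:{depths.ref[i, j]},{depths.alt[i, j]}")
                else:
                    cells.append(gt)
            fh.write(f"1\t{j + 1}\t{locus}\tA\tC\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


def write_dosage_tsv(path: str | Path, dosages: DosageMatrix) -> None:
    df = pd.DataFrame(dosages.dosage, index=dosages.genet_ids, columns=dosages.locus_ids)
    df.index.name = "genet_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return DosageMatrix(
        [str(g) for g in df.index], [str(l) for l in df.columns], df.to_numpy(dtype=float)
    )


def read_membership_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genet_id", "accession_id"} <= set(df.columns):
        raise DataError("membership TSV needs genet_id and accession_id columns")
    return dict(zip(df["genet_id"], df["accession_id"]))


def write_membership_tsv(path: str | Path, membership: Mapping[str, str]) -> None:
    pd.DataFrame(
        sorted(membership.items()), columns=["genet_id", "accession_id"]
    ).to_csv(path, sep="\t", index=False)


def write_profiles_tsv(path: str | Path, profiles: Iterable[AccessionProfile]) -> None:
    profiles = list(profiles)
    ids, mat = profiles_to_matrix(profiles)
    n = {p.accession_id: p.n_genets for p in profiles}
    df = pd.DataFrame(mat, index=ids)
    df.insert(0, "n_genets", [n[a] for a in ids])
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_profiles_tsv(path: str | Path) -> list[AccessionProfile]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return [
        AccessionProfile(str(acc), row.drop("n_genets").to_numpy(dtype=float), int(row["n_genets"]))
        for acc, row in df.iterrows()
    ]
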