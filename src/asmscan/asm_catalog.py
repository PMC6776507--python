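"""Merging, deduplication and filtering of SNP–CpG allele-specific
methylation pair tables from multiple studies and tissues."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATALOG_COLUMNS",
    "CatalogSummary",
    "CoordinateConflictError",
    "CatalogSchemaError",
    "normalize_chrom",
    "read_catalog_table",
    "write_catalog",
    "merge_sources",
    "filter_catalog",
    "probe_overlap_check",
]

CATALOG_COLUMNS = [
    "snp_id",
    "snp_chrom",
    "snp_pos",
    "cpg_id",
    "cpg_chrom",
    "cpg_pos",
    "r2_meth",
    "meth_effect_allele",
    "meth_direction",
    "tissue",
    "study",
]

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


class CatalogSchemaError(ValueError):
    """A catalog table violates the required schema."""


class CoordinateConflictError(ValueError):
    """The same id maps to different coordinates across source tables."""

    def __init__(self, offenders: pd.DataFrame):
        self.offenders = offenders
        ids = sorted(offenders["id"].unique())
        super().__init__(f"conflicting coordinates for ids: {ids}")


@dataclass(frozen=True)
class CatalogSummary:
    """Flow counts for a merged catalog."""

    n_pairs_by_source: dict
    n_pairs_union: int
    n_snps: int
    n_cpgs: int


def normalize_chrom(value) -> str:
    """Normalize a chromosome label: strip a 'chr' prefix, uppercase X/Y."""
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s not in _VALID_CHROMS:
        raise CatalogSchemaError(f"invalid chromosome label: {value!r}")
    return s


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"catalog table missing columns: {missing}")
    out = df.copy()
    out["snp_chrom"] = out["snp_chrom"].map(normalize_chrom)
    out["cpg_chrom"] = out["cpg_chrom"].map(normalize_chrom)
    out["snp_pos"] = out["snp_pos"].astype(int)
    out["cpg_pos"] = out["cpg_pos"].astype(int)
    r2 = out["r2_meth"]
    bad = r2.notna() & ((r2 < 0) | (r2 > 1))
    if bad.any():
        raise CatalogSchemaError(
            f"r2_meth outside [0,1] for pairs: "
            f"{out.loc[bad, ['snp_id', 'cpg_id']].to_dict('records')}"
        )
    return out


def read_catalog_table(path) -> pd.DataFrame:
    """Read one headered TSV of SNP–CpG pairs, normalizing chromosomes."""
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_chrom": str, "cpg_chrom": str, "snp_id": str}
    )
    return _validate(df)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    out = catalog.copy()
    if "sources" in out.columns:
        out["sources"] = out["sources"].map(
            lambda lst: ";".join(f"{st}:{ti}" for st, ti in lst)
        )
    out.to_csv(path, sep="\t", index=False)


def _coordinate_conflicts(df: pd.DataFrame, id_col, chrom_col, pos_col) -> pd.DataFrame:
    coords = df[[id_col, chrom_col, pos_col]].drop_duplicates()
    counts = coords.groupby(id_col).size()
    bad_ids = counts[counts > 1].index
    out = coords[coords[id_col].isin(bad_ids)].copy()
    out.columns = ["id", "chrom", "pos"]
    return out


def merge_sources(
    tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, CatalogSummary]:
    """Union SNP–CpG pairs over distinct ``(snp_id, cpg_id)``.

    Provenance is preserved as a ``sources`` column holding the sorted
    list of distinct ``(study, tissue)`` entries for each pair. When
    duplicate pairs disagree on methylation R², the entry with the
    largest R² supplies the representative R²/effect-allele/direction.

    Raises :class:`CoordinateConflictError` when the same snp_id (or
    cpg_id) carries different coordinates across tables.
    """
    if not tables:
        raise ValueError("merge_sources needs at least one table")
    frames = [_validate(t) for t in tables]
    allrows = pd.concat(frames, ignore_index=True)

    conflicts = pd.concat(
        [
            _coordinate_conflicts(allrows, "snp_id", "snp_chrom", "snp_pos"),
            _coordinate_conflicts(allrows, "cpg_id", "cpg_chrom", "cpg_pos"),
        ],
        ignore_index=True,
    )
    if len(conflicts):
        raise CoordinateConflictError(conflicts)

    by_source = (
        allrows.groupby(["study", "tissue"]).size().to_dict()
    )
    # drop exact duplicate provenance rows before counting provenance
    dedup = allrows.drop_duplicates(subset=["snp_id", "cpg_id", "study", "tissue"])

    records = []
    for (_, _), grp in dedup.groupby(["snp_id", "cpg_id"], sort=True):
        best = grp.sort_values(
            ["r2_meth", "study", "tissue"], ascending=[False, True, True]
        ).iloc[0]
        rec = best[
            [
                "snp_id",
                "snp_chrom",
                "snp_pos",
                "cpg_id",
                "cpg_chrom",
                "cpg_pos",
                "r2_meth",
                "meth_effect_allele",
                "meth_direction",
            ]
        ].to_dict()
        rec["sources"] = sorted(set(zip(grp["study"], grp["tissue"])))
        records.append(rec)
    merged = pd.DataFrame(records)
    if merged.empty:
        merged = pd.DataFrame(
            columns=[c for c in CATALOG_COLUMNS if c not in ("study", "tissue")]
            + ["sources"]
        )
    summary = CatalogSummary(
        n_pairs_by_source={f"{st}/{ti}": int(n) for (st, ti), n in by_source.items()},
        n_pairs_union=len(merged),
        n_snps=merged["snp_id"].nunique(),
        n_cpgs=merged["cpg_id"].nunique(),
    )
    return merged, summary


def filter_catalog(
    catalog: pd.DataFrame,
    min_r2: float = 0.2,
    autosomes_only: bool = True,
    require_cis: bool = True,
    cis_window: int = 1_000_000,
) -> tuple[pd.DataFrame, dict]:
    """Apply the analysis filters in the order cis -> R² -> autosome.

    cis means same chromosome and |snp_pos - cpg_pos| <= ``cis_window``.
    The R² threshold is inclusive (pairs with r2_meth >= ``min_r2`` are
    kept); pairs with missing R² are rejected with reason ``missing_r2``.
    Returns the surviving catalog and an audit log of per-filter removal
    counts in application order.
    """
    df = catalog.copy()
    audit = {"input": len(df)}

    if require_cis:
        same_chrom = df["snp_chrom"] == df["cpg_chrom"]
        near = (df["snp_pos"] - df["cpg_pos"]).abs() <= cis_window
        keep = same_chrom & near
        audit["removed_cis"] = int((~keep).sum())
        df = df[keep]
    else:
        audit["removed_cis"] = 0

    missing = df["r2_meth"].isna()
    audit["removed_missing_r2"] = int(missing.sum())
    low = df["r2_meth"] < min_r2
    audit["removed_low_r2"] = int((low & ~missing).sum())
    df = df[~missing & ~low]

    if autosomes_only:
        keep = df["snp_chrom"].isin(AUTOSOMES)
        audit["removed_non_autosomal"] = int((~keep).sum())
        df = df[keep]
    else:
        audit["removed_non_autosomal"] = 0

    audit["output"] = len(df)
    return df.reset_index(drop=True), audit


def probe_overlap_check(
    catalog: pd.DataFrame,
    variant_positions: pd.DataFrame,
    probe_width: int = 50,
) -> pd.DataFrame:
    """Flag CpGs whose probe footprint contains a known variant.

    The footprint is a window of ``probe_width`` bp centred on
    ``cpg_pos``. ``variant_positions`` needs columns
    ``snp_id, chrom, pos``. Returns one row per distinct CpG with the
    list of overlapping variant ids and a pass flag (empty list = pass).
    """
    half = probe_width // 2
    variants = variant_positions.copy()
    variants["chrom"] = variants["chrom"].map(normalize_chrom)
    cpgs = catalog[["cpg_id", "cpg_chrom", "cpg_pos"]].drop_duplicates("cpg_id")
    rows = []
    for _, cpg in cpgs.iterrows():
        near = variants[
            (variants["chrom"] == cpg["cpg_chrom"])
            & ((variants["pos"] - cpg["cpg_pos"]).abs() <= half)
        ]
        hits = sorted(near["snp_id"])
        rows.append(
            {
                "cpg_id": cpg["cpg_id"],
                "overlapping_variants": hits,
                "n_overlaps": len(hits),
                "pass": len(hits) == 0,
            }
        )
    return pd.DataFrame(rows)
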