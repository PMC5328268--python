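"""Domain types, tabular readers/writers, and inclusion filters.

The analysis population is a long-format table of individually measured
woody plants (one row per individual) joined to per-forest community
metadata.  Two leaf traits are carried: leaf size (individual leaf area,
cm^2) and specific leaf area (SLA, cm^2/g).  An individual may be missing
one trait but not both; a present trait value must be strictly positive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import EmptyDatasetError, MissingColumnError

TRAITS = ("leaf_size", "sla")

#: Default mapping from logical role to column name in input files.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "forest": "forest_id",
    "species": "species_id",
    "individual": "individual_id",
    "leaf_size": "leaf_size",
    "sla": "sla",
}

META_COLUMNS = (
    "forest_id",
    "forest_type",
    "latitude",
    "longitude",
    "mat_c",
    "ap_mm",
    "species_richness",
)


@dataclass
class LoadReport:
    """Bookkeeping for rows excluded while reading a trait table."""

    n_rows_read: int = 0
    n_dropped_invalid_trait: int = 0
    n_dropped_all_missing: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_invalid_trait + self.n_dropped_all_missing


@dataclass
class Dataset:
    """Individual-level trait records plus optional community metadata.

    ``records`` columns: forest_id, species_id, individual_id, leaf_size, sla.
    ``meta`` columns: see :data:`META_COLUMNS` (forest_type/climate columns may
    be absent when only counting operations are needed).
    """

    records: pd.DataFrame
    meta: pd.DataFrame | None = None
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        dup = self.records.duplicated(["forest_id", "species_id", "individual_id"])
        if dup.any():
            bad = self.records.loc[dup.idxmax(), ["forest_id", "species_id", "individual_id"]]
            raise ValueError(
                "duplicate (forest, species, individual) key: " + ", ".join(map(str, bad))
            )
        if self.meta is not None:
            if self.meta["forest_id"].duplicated().any():
                raise ValueError("duplicate forest_id in metadata")
            unknown = set(self.records["forest_id"]) - set(self.meta["forest_id"])
            if unknown:
                raise ValueError(f"records reference forests absent from metadata: {sorted(unknown)!r}")

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in TRAITS:
            raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}")
        return self.records[trait]


def _normalize(df: pd.DataFrame, columns: Mapping[str, str] | None, path) -> tuple[pd.DataFrame, LoadReport]:
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    for role in ("forest", "species"):
        if colmap[role] not in df.columns:
            raise MissingColumnError(colmap[role], str(path))
    present_traits = [t for t in TRAITS if colmap[t] in df.columns]
    if not present_traits:
        raise MissingColumnError(f"{colmap['leaf_size']} or {colmap['sla']}", str(path))

    out = pd.DataFrame(
        {
            "forest_id": df[colmap["forest"]].astype(str),
            "species_id": df[colmap["species"]].astype(str),
        }
    )
    if colmap["individual"] in df.columns:
        out["individual_id"] = df[colmap["individual"]].astype(str)
    else:
        out["individual_id"] = (
            out.groupby(["forest_id", "species_id"]).cumcount().add(1).astype(str)
        )
    for trait in TRAITS:
        if trait in present_traits:
            out[trait] = pd.to_numeric(df[colmap[trait]], errors="coerce")
        else:
            out[trait] = float("nan")

    report = LoadReport(n_rows_read=len(out))
    # a present but non-numeric or non-positive value invalidates the record
    invalid = pd.Series(False, index=out.index)
    for trait in present_traits:
        raw_present = df[colmap[trait]].notna() & (df[colmap[trait]].astype(str).str.strip() != "")
        invalid |= raw_present & (out[trait].isna() | (out[trait] <= 0))
    report.n_dropped_invalid_trait = int(invalid.sum())
    out = out[~invalid]
    all_missing = out[list(TRAITS)].isna().all(axis=1)
    report.n_dropped_all_missing = int(all_missing.sum())
    out = out[~all_missing].reset_index(drop=True)
    return out, report


def read_trait_table(
    path: str | os.PathLike,
    format: str = "auto",
    sheet: int | str = 0,
    columns: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a long-format individual trait table from CSV or a workbook sheet.

    Rows with a present but non-positive or non-numeric trait value are
    dropped and counted in ``Dataset.load_report``; rows missing one of the
    two traits are kept for the other trait's analyses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "workbook" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "workbook":
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.empty:
        raise EmptyDatasetError(f"no data rows in {path}")
    records, report = _normalize(df, columns, path)
    if records.empty:
        raise EmptyDatasetError(f"no valid records in {path}")
    return Dataset(records=records, meta=None, load_report=report)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-forest community metadata table (CSV)."""
    df = pd.read_csv(path)
    for col in ("forest_id", "species_richness"):
        if col not in df.columns:
            raise MissingColumnError(col, str(path))
    df["forest_id"] = df["forest_id"].astype(str)
    if (df["species_richness"] < 1).any():
        raise ValueError("species_richness must be >= 1 for every forest")
    return df


def filter_min_individuals(ds: Dataset, trait: str, k: int = 5) -> Dataset:
    """Keep only (forest, species) groups with >= k non-missing values of ``trait``.

    Grouping is per forest: one species name occurring in two forests forms
    two independent groups. Idempotent.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ds.trait_values(trait)  # validates trait name
    counts = ds.records.groupby(["forest_id", "species_id"])[trait].transform("count")
    kept = ds.records[counts >= k].reset_index(drop=True)
    return Dataset(records=kept, meta=ds.meta)


def count_summary(ds: Dataset) -> dict:
    """Dataset size summary.

    ``n_species`` pools species names across forests; ``n_species_groups``
    counts distinct (forest, species) pairs — both are reported because a
    species occurring in two forests is one name but two analysis groups.
    """
    rec = ds.records
    per_forest = (
        rec.groupby("forest_id")["species_id"].nunique().to_dict() if len(rec) else {}
    )
    return {
        "n_individuals": int(len(rec)),
        "n_species": int(rec["species_id"].nunique()) if len(rec) else 0,
        "n_species_groups": int(len(rec.groupby(["forest_id", "species_id"]))) if len(rec) else 0,
        "n_forests": int(rec["forest_id"].nunique()) if len(rec) else 0,
        "per_forest_species_counts": per_forest,
    }


def write_results_workbook(tables: Mapping[str, pd.DataFrame], path: str | os.PathLike) -> Path:
    """Write named result tables to one multi-sheet workbook or a CSV directory.

    A ``.xlsx`` path yields one sheet per table (rarefied statistics and the
    two overlap-summary layouts mirror the deposited-data sheet schema); any
    other path is treated as a directory receiving ``<name>.csv`` files.
    """
    if not tables:
        raise ValueError("no tables to write")
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            for name, df in tables.items():
                df.to_excel(xl, sheet_name=str(name)[:31], index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(path / f"{name}.csv", index=False)
    return path
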