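"""Occurrence-record schema, ingestion, validation and serialization.

The harmonized dataset is a flat table with one row per species per sample
depth per hole, carrying the full metadata column set (source identifiers,
abundance in original and numeric form, age-model outputs, modern and
paleo-coordinates, drilling metadata, QC flags).  This module defines that
column set, reads heterogeneous per-source CSV tables into it via a
column-mapping config, filters records missing crucial fields, assigns
deterministic identifiers, and writes/reads the final CSV dialect.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Full output column set, in documented order.
COLUMNS: list[str] = [
    "rowID", "db.source", "db.ID", "holeID", "sampleID", "person", "date",
    "species", "orig.species", "orig.abundance", "abundance", "abun.units",
    "total.IDd", "num.ind", "rel.abun",
    "sample.depth", "age", "age.err", "segment", "age.calc",
    "zone", "zon.age", "age.st", "age.en", "rng.age",
    "int.age", "err.int.age",
    "mag.zone", "mag.age", "mag.age.st", "mag.age.en",
    "int.mag.age", "err.int.mag.age",
    "mod.age", "r2", "n.pts", "age.model", "AM.type",
    "latitude", "longitude", "water.depth", "pal.lat", "pal.long",
    "leg", "site", "hole", "core", "section", "sample.top",
    "reason", "sample.type", "processing", "preservation", "trim",
]

#: Columns holding floating-point quantities (everything else is text).
NUMERIC_COLUMNS: frozenset[str] = frozenset({
    "abundance", "total.IDd", "num.ind", "rel.abun", "sample.depth",
    "age", "age.err", "segment", "zon.age", "age.st", "age.en", "rng.age",
    "int.age", "err.int.age", "mag.age", "mag.age.st", "mag.age.en",
    "int.mag.age", "err.int.mag.age", "mod.age", "r2", "n.pts",
    "latitude", "longitude", "water.depth", "pal.lat", "pal.long",
    "sample.top",
})

#: Crucial columns: records missing any of these are removed from the final
#: dataset.  Order fixes the single primary rejection reason per record.
CRUCIAL_RULES: list[tuple[tuple[str, ...], str]] = [
    (("species",), "missing species name"),
    (("abundance",), "missing abundance"),
    (("age",), "missing age"),
    (("pal.lat", "pal.long"), "missing paleocoordinates"),
]


class MappingError(KeyError):
    """A column-mapping config names a column absent from the source table."""


@dataclass
class ValidationReport:
    """Accounting of a validation pass: per-status counts plus the rejected
    rows, each carrying exactly one primary reason."""

    n_input: int
    n_clean: int
    rejects: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["rowID", "reason"]))

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    @property
    def counts(self) -> dict[str, int]:
        out = {"input": self.n_input, "clean": self.n_clean,
               "rejected": self.n_rejected}
        out.update(self.rejects["reason"].value_counts().to_dict())
        return out

    def to_csv(self, path: str | Path) -> None:
        self.rejects.to_csv(path, index=False)


def empty_records(n: int = 0) -> pd.DataFrame:
    """An all-absent record frame with the full schema column set."""
    df = pd.DataFrame({c: [np.nan] * n for c in COLUMNS})
    return coerce_dtypes(df)


def coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce schema columns to float (numeric set) or object/string."""
    df = df.copy()
    for c in df.columns:
        if c in NUMERIC_COLUMNS:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        else:
            df[c] = df[c].astype("object")
            df.loc[df[c].isna(), c] = np.nan
    return df


def _require(columns: Sequence[str], table_cols: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table_cols]
    if missing:
        raise MappingError(
            f"mapping names column(s) absent from source table: {missing}")


def read_occurrence_table(path: str | Path | io.IOBase,
                          mapping: Mapping) -> pd.DataFrame:
    """Read one source CSV into raw schema records.

    ``mapping`` is a per-source config (typically loaded from YAML)::

        db_source: PANGAEA          # source identifier
        db_id: pg0001               # dataset identifier within the source
        format: long | wide
        species: <col>              # long format only
        abundance: <col>            #   "
        depth: <col> | null         # null -> sample.depth absent
        latitude: <col>             # optional; see constants
        longitude: <col>
        hole: <col>                 # optional raw hole/site label column
        id_columns: [<col>, ...]    # wide format: non-species columns
        constants: {latitude: 1.5, ...}   # literal values for all rows
        metadata: {water.depth: <col>, ...}  # extra column pass-through

    Wide tables (samples x species) are melted to long form, one record per
    non-empty cell.  Unmapped metadata is left absent.
    """
    sep = mapping.get("sep", ",")
    try:
        raw = pd.read_csv(path, sep=sep, dtype=object,
                          keep_default_na=False, na_values=["", "NA"])
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise OSError(f"unreadable source table {path!r}: {exc}") from exc

    fmt = mapping.get("format", "long")
    constants = dict(mapping.get("constants", {}))
    meta_map = dict(mapping.get("metadata", {}))

    if fmt == "wide":
        id_cols = list(mapping.get("id_columns", []))
        _require(id_cols, raw.columns)
        sp_cols = [c for c in raw.columns if c not in id_cols]
        long = raw.melt(id_vars=id_cols, value_vars=sp_cols,
                        var_name="__species__", value_name="__abundance__")
        long = long[long["__abundance__"].notna()
                    & (long["__abundance__"].astype(str).str.strip() != "")]
        long = long.reset_index(drop=True)
        species = long["__species__"]
        abundance = long["__abundance__"]
        src = long
    else:
        for key in ("species", "abundance"):
            if key not in mapping:
                raise MappingError(f"long-format mapping must name a "
                                   f"'{key}' column")
        _require([mapping["species"], mapping["abundance"]], raw.columns)
        src = raw
        species = raw[mapping["species"]]
        abundance = raw[mapping["abundance"]]

    n = len(src)
    rec = empty_records(n)
    rec["species"] = species.astype(object).values
    rec["orig.species"] = species.astype(object).values
    rec["orig.abundance"] = abundance.astype(object).values
    rec["db.source"] = mapping.get("db_source", np.nan)
    rec["db.ID"] = mapping.get("db_id", np.nan)

    def pull(schema_col: str, key: str) -> None:
        col = mapping.get(key)
        if col is not None:
            _require([col], src.columns)
            rec[schema_col] = src[col].values

    pull("sample.depth", "depth")
    pull("latitude", "latitude")
    pull("longitude", "longitude")
    pull("hole", "hole")
    pull("sampleID", "sample")
    for schema_col, src_col in meta_map.items():
        _require([src_col], src.columns)
        rec[schema_col] = src[src_col].values
    for schema_col, value in constants.items():
        rec[schema_col] = value
    return coerce_dtypes(rec)


def validate_and_filter(records: pd.DataFrame
                        ) -> tuple[pd.DataFrame, ValidationReport]:
    """Drop records missing any crucial column (species name, abundance,
    age, paleocoordinates).  Every dropped record is accounted for in the
    report with exactly one primary reason (first failing rule wins)."""
    reason = pd.Series(np.nan, index=records.index, dtype=object)
    for cols, label in CRUCIAL_RULES:
        bad = pd.Series(False, index=records.index)
        for c in cols:
            bad |= records[c].isna()
        reason[bad & reason.isna()] = label
    keep = reason.isna()
    clean = records[keep].reset_index(drop=True)
    rejects = pd.DataFrame({
        "rowID": records.loc[~keep, "rowID"].values,
        "reason": reason[~keep].values,
    })
    return clean, ValidationReport(len(records), len(clean), rejects)


def assign_ids(records: pd.DataFrame,
               registry: Mapping[tuple[str, str], str] | None = None
               ) -> pd.DataFrame:
    """Assign holeID, sampleID and rowID deterministically.

    holeID embeds the source so that two holes with the same site label in
    different sources stay distinct; sampleID is the holeID plus a unique
    sample number; rowID combines db.ID, sampleID and a per-row number.
    Records are sorted by (holeID, sample.depth, species) first so IDs are
    stable across re-runs on identical input.
    """
    rec = records.copy()
    if registry:
        for (src, dataset), db_id in registry.items():
            mask = (rec["db.source"] == src) & (rec["db.ID"] == dataset)
            rec.loc[mask, "db.ID"] = db_id
    raw_hole = rec["hole"].fillna("h0").astype(str)
    rec["holeID"] = rec["db.source"].fillna("src").astype(str) + ":" + raw_hole

    rec = rec.sort_values(
        ["holeID", "sample.depth", "species"],
        kind="mergesort", na_position="last").reset_index(drop=True)

    # one sample number per distinct depth within a hole, in depth order
    sample_key = list(zip(rec["holeID"], rec["sample.depth"]))
    seen: dict[tuple, int] = {}
    per_hole: dict[str, int] = {}
    sample_ids = []
    for hole, key in zip(rec["holeID"], sample_key):
        if key not in seen:
            per_hole[hole] = per_hole.get(hole, 0) + 1
            seen[key] = per_hole[hole]
        sample_ids.append(f"{hole}:{seen[key]}")
    rec["sampleID"] = sample_ids

    row_counter: dict[str, int] = {}
    row_ids = []
    for db_id, sid in zip(rec["db.ID"].astype(str), rec["sampleID"]):
        row_counter[sid] = row_counter.get(sid, 0) + 1
        row_ids.append(f"{db_id}:{sid}:{row_counter[sid]}")
    rec["rowID"] = row_ids

    if rec["rowID"].duplicated().any():
        dup = rec.loc[rec["rowID"].duplicated(), "rowID"].iloc[0]
        raise RuntimeError(f"rowID collision after construction: {dup!r}")
    return rec


def write_triton(records: pd.DataFrame, path: str | Path) -> None:
    """Serialize validated records as UTF-8 CSV in the documented column
    order; absent values are written as "NA"."""
    out = records.reindex(columns=COLUMNS)
    out.to_csv(path, index=False, na_rep="NA", encoding="utf-8")


def read_triton(path: str | Path) -> pd.DataFrame:
    """Read a harmonized CSV back; "NA" cells parse as absent."""
    df = pd.read_csv(path, dtype=object, keep_default_na=False,
                     na_values=["NA"], encoding="utf-8")
    return coerce_dtypes(df.reindex(columns=COLUMNS))
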