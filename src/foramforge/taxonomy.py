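"""Taxonomic normalization and synonym resolution.

Raw species names from heterogeneous sources are normalized (whitespace,
capitalization), checked for open-nomenclature qualifiers ("cf.", "aff.",
"?", "sp."), and resolved through a synonymy table to the senior synonym.
Records whose names are invalid, exclusively Mesozoic, not at species level,
or unknown are rejected (unknown names go to a curation log).  Rows of one
sample that resolve to the same senior name are merged with abundances
summed (set to 1 for presence/absence samples), the original names and
abundances retained comma-joined.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Open-nomenclature qualifiers that make a name imprecise.
_QUALIFIER_RE = re.compile(
    r"(?:^|\s)(cf\.?|aff\.?|\?|ex\s+gr\.?|sp{1,2}\.?)(?=\s|$)", re.I)

VALID_STATUSES = {"valid", "junior synonym", "typo", "invalid",
                  "Mesozoic-only", "not-species-level"}
#: Statuses that resolve to a senior name (everything else is a rejection).
RESOLVING = {"valid", "junior synonym", "typo"}


@dataclass(frozen=True)
class NormalizedName:
    name: str
    qualified: bool            # carries cf./aff./?/sp. etc.
    qualifier: str | None = None


@dataclass(frozen=True)
class Resolution:
    senior: str | None         # None -> rejected
    status: str                # synonymy status or rejection reason


def normalize_name(raw: str) -> NormalizedName:
    """Trim and case-normalize a binomial; flag qualifier-bearing names.

    Genus is capitalized, the species epithet lower-cased.  Returns the
    cleaned name even when qualified so the qualifier can be logged.
    Raises ValueError if nothing remains after cleaning.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        raise ValueError("empty species name")
    s = re.sub(r"\s+", " ", str(raw)).strip()
    m = _QUALIFIER_RE.search(s)
    qualifier = m.group(1) if m else None
    if qualifier is not None:
        s = _QUALIFIER_RE.sub(" ", s)
        s = re.sub(r"\s+", " ", s).strip()
    if not s:
        raise ValueError("empty species name after cleaning")
    parts = s.split(" ")
    parts[0] = parts[0].capitalize()
    for i in range(1, len(parts)):
        parts[i] = parts[i].lower()
    # "Genus sp."-type names lose the epithet entirely -> not species level
    qualified = qualifier is not None
    return NormalizedName(" ".join(parts), qualified, qualifier)


class SynonymyTable:
    """Maps raw names to senior synonyms with a status per entry.

    Resolution is a function: each raw name has exactly one senior name, and
    a senior name resolves to itself (no chains).  Senior names of resolving
    entries must appear in the valid-species list.
    """

    def __init__(self, entries: pd.DataFrame,
                 valid_species: set[str] | None = None):
        entries = entries.copy()
        entries.columns = [c.strip() for c in entries.columns]
        required = {"raw", "senior", "status"}
        if not required <= set(entries.columns):
            raise ValueError(f"synonymy table needs columns {required}")
        bad = set(entries["status"]) - VALID_STATUSES
        if bad:
            raise ValueError(f"unknown synonymy statuses: {bad}")
        if entries["raw"].duplicated().any():
            dup = entries.loc[entries["raw"].duplicated(), "raw"].iloc[0]
            raise ValueError(f"raw name maps to multiple entries: {dup!r}")
        self._map = {r.raw: (r.senior, r.status)
                     for r in entries.itertuples(index=False)}
        if valid_species is None:
            valid_species = {s for s, st in self._map.values()
                             if st in RESOLVING}
        self.valid_species = set(valid_species)
        for raw, (senior, status) in self._map.items():
            if status in RESOLVING:
                if senior not in self.valid_species:
                    raise ValueError(
                        f"senior name {senior!r} not in valid-species list")
                chained = self._map.get(senior)
                if chained is not None and chained[0] != senior:
                    raise ValueError(f"synonymy chain via {senior!r}")

    @classmethod
    def from_csv(cls, path: str | Path,
                 valid_species_path: str | Path | None = None
                 ) -> "SynonymyTable":
        entries = pd.read_csv(path)
        valid = None
        if valid_species_path is not None:
            valid = set(pd.read_csv(valid_species_path)["species"])
        return cls(entries, valid)

    def resolve(self, name: str) -> Resolution:
        """Senior name for a normalized raw name, or a rejection."""
        hit = self._map.get(name)
        if hit is None:
            return Resolution(None, "unknown name")
        senior, status = hit
        if status in RESOLVING:
            return Resolution(senior, status)
        return Resolution(None, status)


def apply_taxonomy(records: pd.DataFrame, table: SynonymyTable
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize and resolve every record's species name.

    Returns (resolved records, curation log).  Rejected records (qualified
    names, invalid/Mesozoic/not-species-level statuses, unknown names) are
    removed; the log lists one row per rejection with the raw name and
    reason, unknown names flagged for curation.
    """
    keep = np.ones(len(records), dtype=bool)
    seniors: list[str | None] = []
    log_rows = []
    for i, raw in enumerate(records["species"]):
        try:
            norm = normalize_name(raw)
        except ValueError:
            keep[i] = False
            seniors.append(None)
            log_rows.append((raw, "empty name"))
            continue
        if norm.qualified:
            keep[i] = False
            seniors.append(None)
            if norm.qualifier.rstrip(".").lower() in ("sp", "spp"):
                log_rows.append((raw, "not-species-level"))
            else:
                log_rows.append((raw, f"imprecise name ({norm.qualifier})"))
            continue
        res = table.resolve(norm.name)
        if res.senior is None:
            keep[i] = False
            seniors.append(None)
            log_rows.append((raw, res.status))
            continue
        seniors.append(res.senior)
    out = records[keep].copy()
    out["species"] = [s for s in seniors if s is not None]
    log = pd.DataFrame(log_rows, columns=["raw", "reason"])
    return out.reset_index(drop=True), log


def merge_synonym_rows(records: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse same-sample rows that resolved to one senior name.

    Numeric abundances are summed; presence/absence samples get merged
    abundance 1; orig.species / orig.abundance are comma-joined in a
    canonical (sorted-by-original-name) order so merging is order
    independent.  Samples mixing abundance units are quarantined and
    reported in the error frame instead of merged.
    """
    if records.empty:
        return records.copy(), pd.DataFrame(columns=["sampleID", "error"])
    errors = []
    kept = []
    for sid, grp in records.groupby("sampleID", sort=True, dropna=False):
        units = grp["abun.units"].dropna().unique()
        if len(units) > 1:
            errors.append((sid, f"mixed abundance units {sorted(units)}"))
            continue
        unit = units[0] if len(units) else None
        for _, sub in grp.groupby("species", sort=True):
            if len(sub) == 1:
                kept.append(sub.iloc[0])
                continue
            order = np.argsort(sub["orig.species"].astype(str).values,
                               kind="stable")
            sub = sub.iloc[order]
            row = sub.iloc[0].copy()
            if unit == "P/A":
                row["abundance"] = 1.0
            else:
                row["abundance"] = float(sub["abundance"].sum())
            row["orig.species"] = ", ".join(sub["orig.species"].astype(str))
            row["orig.abundance"] = ", ".join(
                sub["orig.abundance"].astype(str))
            kept.append(row)
    merged = pd.DataFrame(kept).reset_index(drop=True)
    return merged, pd.DataFrame(errors, columns=["sampleID", "error"])
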