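"""Marker-event calibration and depth-age tie points.

Biostratigraphic zone boundaries are defined by marker events (first/last
occurrences, acmes) of index taxa, and magnetostratigraphic reversals by
chron boundaries; both carry timescale-calibrated age intervals that can
depend on the zonal scheme and on the ocean basin / latitude band of the
site.  This module resolves raw event labels against a calibrated event
table (scheme- and region-aware, with a global fallback), disambiguates the
"LO" abbreviation from the full event list of a study, places events at
depth by the midpoint rule between the bracketing samples, and adds a 0 Ma
seafloor tie where the sediment surface is declared Holocene/Recent/Modern.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("Atlantic-tropical", "Atlantic-temperate",
           "IndoPacific-tropical", "IndoPacific-temperate", "global")

EVENT_TYPES = ("first occurrence", "last occurrence",
               "acme base", "acme top",
               "magnetochron base", "magnetochron top")

#: Event types observed as the downcore *start* of a presence interval
#: (the feature appears above this depth going up? no: it appears at this
#: depth and persists upcore), vs. the upcore *end* of one.
_BASE_TYPES = {"first occurrence", "acme base", "magnetochron base"}
_TOP_TYPES = {"last occurrence", "acme top", "magnetochron top"}

TROPICAL_LIMIT = 23.5          # |lat| <= limit -> tropical (inclusive)
ATLANTIC_LON = (-70.0, 20.0)   # default basin boundary, configurable

HOLOCENE_FLAGS = {"holocene", "recent", "modern"}


@dataclass(frozen=True)
class MarkerEvent:
    """A calibrated datum: taxon or chron, event type, and its age interval
    (older bound first) under a zonal scheme and region."""
    label: str                    # taxon or chron name
    event_type: str
    scheme: str
    region: str
    age_st: float                 # older bound, Ma
    age_en: float                 # younger bound, Ma

    def __post_init__(self):
        if not (self.age_st >= self.age_en >= 0):
            raise ValueError(
                f"event ages must satisfy age.st >= age.en >= 0, got "
                f"({self.age_st}, {self.age_en})")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_st + self.age_en)

    @property
    def width(self) -> float:
        return self.age_st - self.age_en

    @property
    def kind(self) -> str:
        return ("magnetostratigraphic"
                if self.event_type.startswith("magnetochron")
                else "biostratigraphic")


@dataclass(frozen=True)
class TiePoint:
    """A depth-age anchor for an age-depth model."""
    hole: str
    depth: float                  # mbsf, >= 0
    age: float                    # Ma (event interval midpoint)
    age_range: float              # Ma (event interval width)
    kind: str                     # biostratigraphic|magnetostratigraphic|seafloor
    source: str = ""              # event label, for diagnostics

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("tie depth must be >= 0")


def assign_region(latitude: float, longitude: float,
                  atlantic_lon: tuple[float, float] = ATLANTIC_LON) -> str:
    """Basin x latitude-band region of a site.

    Atlantic is the longitude band ``atlantic_lon`` (default 70W-20E);
    tropical iff |lat| <= 23.5 (boundary inclusive).
    """
    lo, hi = atlantic_lon
    basin = "Atlantic" if lo <= longitude <= hi else "IndoPacific"
    band = "tropical" if abs(latitude) <= TROPICAL_LIMIT else "temperate"
    return f"{basin}-{band}"


class EventTable:
    """Calibrated marker events keyed by (label, event type, scheme, region).

    Mirrors a timescale-conversion deposit: CSV columns ``label, event.type,
    scheme, region, age.st, age.en`` (extra columns pass through).  A
    region-specific entry is preferred over a ``global`` one; contradictory
    duplicates (same key, different ages) are fatal at load.
    """

    def __init__(self, table: pd.DataFrame):
        t = table.copy()
        need = {"label", "event.type", "scheme", "region",
                "age.st", "age.en"}
        if not need <= set(t.columns):
            raise ValueError(f"event table needs columns {need}")
        key = ["label", "event.type", "scheme", "region"]
        dup = t.duplicated(subset=key, keep=False)
        if dup.any():
            contradictory = (t[dup].groupby(key)[["age.st", "age.en"]]
                             .nunique() > 1).any(axis=1)
            if contradictory.any():
                raise ValueError("contradictory duplicate event entries: "
                                 f"{contradictory[contradictory].index.tolist()}")
            t = t.drop_duplicates(subset=key)
        self._table = t

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        return cls(pd.read_csv(path))

    def calibrate(self, label: str, event_type: str, scheme: str,
                  region: str) -> MarkerEvent | None:
        """Resolve an event to its calibrated ages; None if unresolvable
        (caller logs and drops it from the age model)."""
        t = self._table
        hit = t[(t["label"] == label) & (t["event.type"] == event_type)
                & (t["scheme"] == scheme)]
        if hit.empty:   # scheme-free fallback: unique label+type entry
            hit = t[(t["label"] == label) & (t["event.type"] == event_type)]
            if hit["scheme"].nunique() > 1:
                return None
        regional = hit[hit["region"] == region]
        chosen = regional if len(regional) else hit[hit["region"] == "global"]
        if len(chosen) != 1:
            return None
        row = chosen.iloc[0]
        return MarkerEvent(label, event_type, row["scheme"], row["region"],
                           float(row["age.st"]), float(row["age.en"]))


def interpret_lo(codes: Iterable[str]) -> str:
    """Disambiguate "LO" from a study's full abbreviation list.

    If the list contains both LO and HO, LO reads "lowest occurrence"
    (= first occurrence) and HO "highest occurrence"; if it mixes FO with
    LO, LO reads "last occurrence".  A lone LO defaults to last occurrence
    (the commoner modern usage).
    """
    codeset = {c.upper() for c in codes}
    if "LO" in codeset and "HO" in codeset:
        return "first occurrence"
    return "last occurrence"


def resolve_event_codes(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Map raw event strings like "LO Globorotalia tumida" to
    (taxon, event type) pairs, LO/HO read in the context of the whole list."""
    codes = [lab.split(" ", 1)[0] for lab in labels]
    lo_meaning = interpret_lo(codes)
    mapping = {
        "FO": "first occurrence", "FAD": "first occurrence",
        "B": "first occurrence", "BASE": "first occurrence",
        "LAD": "last occurrence", "T": "last occurrence",
        "TOP": "last occurrence", "HO": "last occurrence",
        "LO": lo_meaning,
    }
    out = []
    for lab in labels:
        code, _, rest = lab.partition(" ")
        etype = mapping.get(code.upper())
        if etype is None or not rest:
            out.append((lab, ""))     # unresolvable; caller drops
        else:
            out.append((rest.strip(), etype))
    return out


def tie_from_occurrences(event: MarkerEvent, hole: str,
                         depths: Sequence[float],
                         present: Sequence[bool]) -> TiePoint | None:
    """Place an event at depth by the midpoint rule.

    ``depths`` ascend (shallow to deep).  For a last occurrence / top event
    the tie depth is midway between the shallowest sample containing the
    taxon and the deepest sample above it from which it is absent; for a
    first occurrence / base event, midway between the deepest presence and
    the first absence below.  Returns None (no bracket) when the taxon is
    present in every sample or the transition is not expressed.
    """
    d = np.asarray(depths, dtype=float)
    p = np.asarray(present, dtype=bool)
    if len(d) != len(p):
        raise ValueError("depths and presence flags differ in length")
    if not (np.diff(d) > 0).all():
        raise ValueError("depths must be strictly increasing")
    if not p.any():
        return None
    idx = np.flatnonzero(p)
    if event.event_type in _TOP_TYPES:
        i = idx[0]                      # shallowest presence
        if i == 0:
            return None                 # present to the top: no bracket
        j = i - 1                       # first absence upcore
    else:
        i = idx[-1]                     # deepest presence
        if i == len(d) - 1:
            return None                 # present to the bottom: no bracket
        j = i + 1                       # first absence downcore
    depth = 0.5 * (d[i] + d[j])
    return TiePoint(hole, depth, event.age_mid, event.width,
                    event.kind, event.label)


def add_seafloor_tie(hole: str, surface_age_flag: str | None
                     ) -> TiePoint | None:
    """0 Ma tie at 0 mbsf iff the sediment surface is declared
    Holocene/Recent/Modern; otherwise no tie."""
    if surface_age_flag is None:
        return None
    if str(surface_age_flag).strip().lower() in HOLOCENE_FLAGS:
        return TiePoint(hole, 0.0, 0.0, 0.0, "seafloor", "sediment surface")
    return None
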