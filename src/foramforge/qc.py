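"""Quality control: cross-source deduplication and out-of-range trimming.

Integrating multiple sources inevitably duplicates records; records
identical on (species, numeric abundance, sample depth, latitude,
longitude) are collapsed to one, keeping the copy from the highest-priority
source.  Separately, occurrences falling significantly outside a species'
known stratigraphic range — more than 2 Ma outside in the Neogene
(age < 23 Ma) or 5 Ma in the Paleogene — are flagged for exclusion
(trim = "exc") as likely misidentifications, contamination or reworking;
they are flagged, never deleted, so users choose their own cut-off.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Equality tolerance on harmonized numeric abundance (decimal places).
DUPLICATE_DECIMALS = 9

NEOGENE_BOUNDARY = 23.0       # Ma; age < boundary -> Neogene rule
NEOGENE_TOLERANCE = 2.0       # Ma outside range tolerated in the Neogene
PALEOGENE_TOLERANCE = 5.0     # Ma outside range tolerated in the Paleogene

#: Default source priority, highest first: compilation databases, then
#: drilling-report extractions, then literature compilations.
DEFAULT_PRIORITY: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpeciesRange:
    """Known stratigraphic range of a species (ages in Ma, speciation is
    the older bound)."""
    species: str
    speciation: float
    extinction: float

    def __post_init__(self):
        if not (self.speciation >= self.extinction >= 0):
            raise ValueError(
                f"{self.species}: speciation >= extinction >= 0 required")


def load_species_ranges(path: str | Path) -> dict[str, SpeciesRange]:
    """Species-range CSV with columns species, speciation, extinction."""
    df = pd.read_csv(path)
    return {r.species: SpeciesRange(r.species, float(r.speciation),
                                    float(r.extinction))
            for r in df.itertuples(index=False)}


def drop_duplicates(records: pd.DataFrame,
                    source_priority: Sequence[str] = DEFAULT_PRIORITY
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cross-source duplicates.

    Duplicates are records identical on (species, abundance to 1e-9,
    sample.depth, latitude, longitude); the copy from the earliest source
    in ``source_priority`` survives (unlisted sources rank below listed
    ones, ties broken by rowID for determinism).  Returns the deduplicated
    frame and a per-source-pair removal log.
    """
    out = records.copy()
    rank = {s: i for i, s in enumerate(source_priority)}
    out["_rank"] = [rank.get(s, len(rank)) for s in out["db.source"]]
    key_cols = ["species", "_ab", "sample.depth", "latitude", "longitude"]
    out["_ab"] = out["abundance"].astype(float).round(DUPLICATE_DECIMALS)
    order = out.sort_values(["_rank", "rowID"], kind="mergesort")
    keep_idx = order.drop_duplicates(subset=key_cols, keep="first").index
    removed = out.loc[~out.index.isin(keep_idx)]

    log_rows = []
    if len(removed):
        kept_map = order.drop_duplicates(subset=key_cols, keep="first") \
            .set_index(pd.MultiIndex.from_frame(
                order.drop_duplicates(subset=key_cols,
                                      keep="first")[key_cols]))
        kept_source = {tuple(k): s for k, s in
                       zip(kept_map.index, kept_map["db.source"])}
        pair_counts: dict[tuple, int] = {}
        for _, row in removed.iterrows():
            key = tuple(row[c] for c in key_cols)
            pair = (kept_source.get(key), row["db.source"])
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
        log_rows = [(kept, dropped, n)
                    for (kept, dropped), n in sorted(pair_counts.items(),
                                                     key=str)]
    clean = out.loc[out.index.isin(keep_idx)] \
        .drop(columns=["_rank", "_ab"]) \
        .sort_index().reset_index(drop=True)
    log = pd.DataFrame(log_rows,
                       columns=["kept.source", "dropped.source", "n"])
    return clean, log


def trim_tolerance(age: float,
                   neogene_boundary: float = NEOGENE_BOUNDARY,
                   neogene_t: float = NEOGENE_TOLERANCE,
                   paleogene_t: float = PALEOGENE_TOLERANCE) -> float:
    """Out-of-range tolerance for a record of a given age (era keyed to the
    record's assigned age; Neogene side strict at the 23 Ma boundary)."""
    return neogene_t if age < neogene_boundary else paleogene_t


def flag_trim(records: pd.DataFrame,
              ranges: Mapping[str, SpeciesRange],
              neogene_t: float = NEOGENE_TOLERANCE,
              paleogene_t: float = PALEOGENE_TOLERANCE
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set trim = "exc" for records more than the era tolerance outside
    their species' known range, "inc" otherwise.

    Species without a known range stay "inc" and are listed in the log.
    """
    out = records.copy()
    flags = []
    log_rows = []
    unknown_logged = set()
    for _, row in out.iterrows():
        sp, age = row["species"], row["age"]
        rng = ranges.get(sp)
        if rng is None:
            if sp not in unknown_logged:
                log_rows.append((sp, "no known range; kept inc"))
                unknown_logged.add(sp)
            flags.append("inc")
            continue
        if pd.isna(age):
            flags.append("inc")
            continue
        t = trim_tolerance(float(age), neogene_t=neogene_t,
                           paleogene_t=paleogene_t)
        outside = (age > rng.speciation + t) or (age < rng.extinction - t)
        flags.append("exc" if outside else "inc")
    out["trim"] = flags
    return out, pd.DataFrame(log_rows, columns=["species", "note"])
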