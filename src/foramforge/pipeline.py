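"""End-to-end orchestration of the harmonization stages.

Order of operations mirrors the data-processing sequence the schema
implies: ingest per-source tables, assign identifiers, resolve taxonomy,
convert abundances to numeric (synonym merging happens before relative
abundances so percentages reflect merged taxa), split off zero-abundance
rows, remove cross-source duplicates, fit age-depth models and assign
ages, rotate to paleocoordinates, flag out-of-range records, and finally
drop records missing any crucial column.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import abundance as ab
from . import schema_io
from .age_model import AgeDepthModel, assign_ages
from .chronology import TiePoint
from .paleogeo import RotationTable, paleocoordinates
from .qc import SpeciesRange, drop_duplicates, flag_trim
from .taxonomy import SynonymyTable, apply_taxonomy, merge_synonym_rows


@dataclass
class PipelineResult:
    records: pd.DataFrame                 # final clean dataset
    full: pd.DataFrame                    # including zero-abundance rows
    models: dict[str, AgeDepthModel]
    report: schema_io.ValidationReport
    logs: dict[str, pd.DataFrame] = field(default_factory=dict)


def ingest_sources(sources: Mapping[str, tuple], registry=None
                   ) -> pd.DataFrame:
    """Read every source table (path or in-memory frame) through its
    mapping and assign identifiers across the combined set."""
    frames = []
    for name in sorted(sources):
        table, mapping = sources[name]
        if isinstance(table, pd.DataFrame):
            buf = io.StringIO()
            table.to_csv(buf, index=False)
            buf.seek(0)
            table = buf
        frames.append(schema_io.read_occurrence_table(table, mapping))
    raw = pd.concat(frames, ignore_index=True)
    return schema_io.assign_ids(raw, registry)


def harmonize_abundances(records: pd.DataFrame,
                         synonymy: SynonymyTable | None = None,
                         vocab_overrides: Mapping | None = None
                         ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Taxonomy resolution, numeric conversion, synonym-row merging and
    relative abundances, per sample."""
    logs: dict[str, pd.DataFrame] = {}
    rec = records.copy()
    if synonymy is not None:
        rec, logs["taxonomy"] = apply_taxonomy(rec, synonymy)

    pieces = []
    for sid, grp in rec.groupby("sampleID", sort=True):
        vocab = (vocab_overrides or {}).get(grp["db.ID"].iloc[0])
        units, inconsistent = ab.classify_units(
            grp["orig.abundance"].tolist(), vocab)
        grp = grp.copy()
        grp["abun.units"] = units
        grp["abundance"] = [
            ab.to_numeric(v, units, vocab, bool(f))
            for v, f in zip(grp["orig.abundance"], inconsistent)]
        pieces.append(grp)
    rec = pd.concat(pieces, ignore_index=True)

    rec, merge_errors = merge_synonym_rows(rec)
    logs["merge_errors"] = merge_errors

    pieces = []
    for sid, grp in rec.groupby("sampleID", sort=True):
        total = grp["total.IDd"].dropna()
        pieces.append(ab.relative_abundance(
            grp, float(total.iloc[0]) if len(total) else None))
    rec = pd.concat(pieces, ignore_index=True)
    return schema_io.coerce_dtypes(rec), logs


def _raw_hole(hole_id: str) -> str:
    return hole_id.split(":", 1)[1] if ":" in str(hole_id) else str(hole_id)


def model_ages(records: pd.DataFrame,
               ties_by_hole: Mapping[str, Sequence[TiePoint]],
               overrides: Mapping[str, str] | None = None,
               declared_breaks: Mapping[str, Sequence[float]] | None = None
               ) -> tuple[pd.DataFrame, dict[str, AgeDepthModel],
                          pd.DataFrame]:
    """Fit an age-depth model per hole and assign sample ages.

    ``ties_by_hole`` is keyed by the raw hole label (shared across sources
    describing the same hole).  Records of holes without ties, or outside
    every segment's tie span, are dropped with a logged reason.
    """
    overrides = overrides or {}
    declared_breaks = declared_breaks or {}
    models: dict[str, AgeDepthModel] = {}
    kept, dropped = [], []
    for hole_id, grp in records.groupby("holeID", sort=True):
        raw = _raw_hole(hole_id)
        ties = ties_by_hole.get(raw)
        if not ties:
            dropped.extend((rid, "no tie points for hole")
                           for rid in grp["rowID"])
            continue
        if raw not in models:
            models[raw] = AgeDepthModel.fit(
                raw, ties, declared_breaks.get(raw, ()),
                overrides.get(raw))
        aged, drops = assign_ages(grp, models[raw])
        kept.append(aged)
        dropped.extend(drops.itertuples(index=False, name=None))
    out = (pd.concat(kept, ignore_index=True) if kept
           else schema_io.empty_records())
    return out, models, pd.DataFrame(dropped, columns=["rowID", "reason"])


def process_corpus(sources: Mapping[str, tuple],
                   ties_by_hole: Mapping[str, Sequence[TiePoint]],
                   rotation_table: RotationTable,
                   plate_by_hole: Mapping[str, int],
                   species_ranges: Mapping[str, SpeciesRange] | None = None,
                   synonymy: SynonymyTable | None = None,
                   source_priority: Sequence[str] = (),
                   vocab_overrides: Mapping | None = None,
                   model_overrides: Mapping[str, str] | None = None
                   ) -> PipelineResult:
    """Run the full harmonization pipeline over a multi-source corpus."""
    rec = ingest_sources(sources)
    rec, logs = harmonize_abundances(rec, synonymy, vocab_overrides)
    rec, full = ab.split_zero_abundance(rec)
    rec, logs["duplicates"] = drop_duplicates(rec, source_priority)
    rec, models, logs["undated"] = model_ages(rec, ties_by_hole,
                                              model_overrides)
    plate_ids = {hid: plate_by_hole.get(_raw_hole(hid))
                 for hid in rec["holeID"].unique()}
    plate_ids = {k: v for k, v in plate_ids.items() if v is not None}
    rec, logs["rotation"] = paleocoordinates(rec, rotation_table, plate_ids)
    if species_ranges is not None:
        rec, logs["trim"] = flag_trim(rec, species_ranges)
    rec, report = schema_io.validate_and_filter(rec)
    return PipelineResult(rec, full, models, report, logs)


def identity_rotation_table(plates: Sequence[int],
                            max_age: float = 200.0) -> RotationTable:
    """A rotation model in which every plate is fixed to the anchor
    (synthetic corpora use this: paleo = modern coordinates)."""
    rows = []
    for p in plates:
        for age in (0.0, max_age):
            rows.append({"moving": int(p), "age": age, "pole_lat": 90.0,
                         "pole_lon": 0.0, "angle": 0.0, "fixed": 1})
    return RotationTable(pd.DataFrame(rows))
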