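import io

import numpy as np
import pandas as pd
import pytest

from foramforge import schema_io
from conftest import make_records


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text)


WIDE = """depth,Globigerina bulloides,Orbulina universa,Globigerinoides ruber
1.0,10,,5
2.0,3,7,
"""

LONG = """Species,Count,Depth [m]
Globigerina bulloides,10,1.0
Orbulina universa,7,2.0
Globigerinoides ruber,5,1.0
"""


class TestReadOccurrenceTable:
    def test_wide_table_melts_one_record_per_nonempty_cell(self):
        mapping = {"format": "wide", "id_columns": ["depth"],
                   "depth": "depth", "db_source": "S", "db_id": "d1"}
        rec = schema_io.read_occurrence_table(_csv(WIDE), mapping)
        assert len(rec) == 4          # cell count preserved
        assert set(rec["species"]) == {"Globigerina bulloides",
                                       "Orbulina universa",
                                       "Globigerinoides ruber"}
        assert rec["sample.depth"].notna().all()

    def test_long_table_and_toy_cell_count(self):
        mapping = {"format": "long", "species": "Species",
                   "abundance": "Count", "depth": "Depth [m]"}
        rec = schema_io.read_occurrence_table(_csv(LONG), mapping)
        assert len(rec) == 3
        assert rec.loc[0, "orig.abundance"] == "10"

    def test_missing_depth_mapping_leaves_depth_absent(self):
        mapping = {"format": "long", "species": "Species",
                   "abundance": "Count"}
        rec = schema_io.read_occurrence_table(_csv(LONG), mapping)
        assert rec["sample.depth"].isna().all()

    def test_mapping_naming_absent_column_is_fatal_with_name(self):
        mapping = {"format": "long", "species": "Species",
                   "abundance": "NoSuchColumn"}
        with pytest.raises(schema_io.MappingError, match="NoSuchColumn"):
            schema_io.read_occurrence_table(_csv(LONG), mapping)

    def test_constants_fill_every_row(self):
        mapping = {"format": "long", "species": "Species",
                   "abundance": "Count",
                   "constants": {"latitude": -12.5, "hole": "H9"}}
        rec = schema_io.read_occurrence_table(_csv(LONG), mapping)
        assert (rec["latitude"] == -12.5).all()
        assert (rec["hole"] == "H9").all()


class TestValidateAndFilter:
    def test_crucial_column_filtering_accounts_for_every_record(self):
        rows = [{"rowID": f"r{i}", "species": "A", "abundance": 1.0,
                 "age": 2.0, "pal.lat": 0.0, "pal.long": 0.0}
                for i in range(10)]
        for i in range(3):
            rows[i]["species"] = np.nan
        rec = make_records(rows)
        clean, report = schema_io.validate_and_filter(rec)
        assert len(clean) == 7
        assert report.n_rejected == 3
        assert (report.rejects["reason"] == "missing species name").all()
        assert report.n_input == len(clean) + report.n_rejected

    def test_missing_age_reason_and_one_primary_reason_each(self):
        rec = make_records([
            {"rowID": "a", "species": "X", "abundance": 1.0,
             "pal.lat": 0.0, "pal.long": 0.0},                 # no age
            {"rowID": "b", "species": "X", "abundance": 1.0,
             "age": 1.0, "pal.lat": 0.0, "pal.long": 0.0},     # complete
        ])
        clean, report = schema_io.validate_and_filter(rec)
        assert list(clean["rowID"]) == ["b"]
        assert report.rejects.iloc[0]["reason"] == "missing age"

    def test_idempotent(self):
        rec = make_records([
            {"rowID": "a", "species": "X", "abundance": 1.0, "age": 1.0,
             "pal.lat": 0.0, "pal.long": 0.0},
            {"rowID": "b", "abundance": 1.0, "age": 1.0,
             "pal.lat": 0.0, "pal.long": 0.0},
        ])
        once, _ = schema_io.validate_and_filter(rec)
        twice, rep2 = schema_io.validate_and_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_rejected == 0


class TestAssignIds:
    def _raw(self):
        return make_records([
            {"db.source": "SRC", "db.ID": "d1", "hole": "H",
             "sample.depth": 1.0, "species": "B sp1", "abundance": 1.0},
            {"db.source": "SRC", "db.ID": "d1", "hole": "H",
             "sample.depth": 1.0, "species": "A sp2", "abundance": 2.0},
            {"db.source": "SRC", "db.ID": "d1", "hole": "H",
             "sample.depth": 2.0, "species": "A sp2", "abundance": 2.0},
        ])

    def test_same_sample_shares_sampleid_distinct_rowids(self):
        rec = schema_io.assign_ids(self._raw())
        s1 = rec[rec["sample.depth"] == 1.0]
        assert s1["sampleID"].nunique() == 1
        assert s1["rowID"].nunique() == 2

    def test_rerun_is_deterministic_under_permutation(self):
        rec1 = schema_io.assign_ids(self._raw())
        shuffled = self._raw().sample(frac=1, random_state=7)
        rec2 = schema_io.assign_ids(shuffled)
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_same_site_name_in_two_sources_gets_distinct_holeids(self):
        rows = self._raw()
        other = rows.copy()
        other["db.source"] = "OTHER"
        rec = schema_io.assign_ids(pd.concat([rows, other],
                                             ignore_index=True))
        assert rec["holeID"].nunique() == 2

    def test_rowid_embeds_dataset_and_sample_ids(self):
        rec = schema_io.assign_ids(self._raw())
        for _, r in rec.iterrows():
            assert r["rowID"].startswith(f'{r["db.ID"]}:{r["sampleID"]}')


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rec = schema_io.assign_ids(make_records([
            {"db.source": "S", "db.ID": "d", "hole": "H",
             "sample.depth": 1.0, "species": "Orbulina universa",
             "abundance": 3.0, "age": 1.25, "latitude": -4.5,
             "trim": "inc"},
        ]))
        path = tmp_path / "out.csv"
        schema_io.write_triton(rec, path)
        back = schema_io.read_triton(path)
        pd.testing.assert_frame_equal(rec.reindex(columns=schema_io.COLUMNS),
                                      back)

    def test_absent_values_serialize_as_na_and_parse_back(self, tmp_path):
        rec = make_records([{"species": "X", "abundance": 1.0}])
        path = tmp_path / "na.csv"
        schema_io.write_triton(rec, path)
        text = path.read_text()
        assert ",NA," in text
        back = schema_io.read_triton(path)
        assert back["age"].isna().all()

    def test_empty_record_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        schema_io.write_triton(schema_io.empty_records(), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",")[0] == "rowID"
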