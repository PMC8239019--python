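import numpy as np
import pandas as pd
import pytest

from foramforge import schema_io
from foramforge.chronology import TiePoint
from foramforge.qc import SpeciesRange
from foramforge.taxonomy import SynonymyTable


@pytest.fixture
def synonymy() -> SynonymyTable:
    entries = pd.DataFrame([
        # raw, senior, status
        ("Globorotalia flexuosa", "Globorotalia flexuosa", "valid"),
        ("Globototalia flexuosa", "Globorotalia flexuosa", "typo"),
        ("Globorotalia menardii", "Globorotalia menardii", "valid"),
        ("Globorotalia cultrata", "Globorotalia menardii",
         "junior synonym"),
        ("Fohsella fohsi", "Fohsella fohsi", "valid"),
        ("Hedbergella holmdelensis", "Hedbergella holmdelensis",
         "Mesozoic-only"),
        ("Globigerina bulloides", "Globigerina bulloides", "valid"),
        ("Globigerinoides ruber", "Globigerinoides ruber", "valid"),
        ("Orbulina universa", "Orbulina universa", "valid"),
    ], columns=["raw", "senior", "status"])
    return SynonymyTable(entries)


@pytest.fixture
def event_table_frame() -> pd.DataFrame:
    rows = [
        # label, event.type, scheme, region, age.st, age.en
        ("M8", "zone base", "Berggren95", "global", 12.9, 12.6),
        ("M9", "zone base", "Wade11", "global", 12.9, 12.6),
        ("Globorotalia tumida", "first occurrence", "Wade11",
         "global", 5.8, 5.6),
        ("Globorotalia tumida", "first occurrence", "Wade11",
         "IndoPacific-tropical", 6.1, 5.9),
        ("Globigerinoides ruber", "first occurrence", "Wade11",
         "global", 8.6, 8.4),
        ("C3n", "magnetochron base", "GTS2020", "global", 5.24, 5.24),
    ]
    return pd.DataFrame(rows, columns=["label", "event.type", "scheme",
                                       "region", "age.st", "age.en"])


@pytest.fixture
def species_ranges() -> dict[str, SpeciesRange]:
    return {
        "Neogenica recens": SpeciesRange("Neogenica recens", 20.0, 10.0),
        "Paleogenica vetus": SpeciesRange("Paleogenica vetus", 40.0, 30.0),
    }


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a schema frame from sparse row dicts (absent -> NaN)."""
    rec = schema_io.empty_records(len(rows))
    for i, row in enumerate(rows):
        for col, val in row.items():
            rec.loc[i, col] = val
    return schema_io.coerce_dtypes(rec)


@pytest.fixture
def linear_ties() -> list[TiePoint]:
    # 20 m/Ma constant-rate hole, ties every 10 m / 0.5 Ma
    return [TiePoint("H1", float(d), d / 20.0, 0.2, "biostratigraphic",
                     f"e{i}")
            for i, d in enumerate(np.arange(0.0, 101.0, 10.0))]
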