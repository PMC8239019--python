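"""Abundance harmonization.

Source datasets record abundance in five ways: presence/absence, binned
(ordinal letter codes), relative abundance (percent), raw specimen counts,
and number of specimens per gram.  All are converted to a numeric
``abundance`` column; counts, relative and per-gram values additionally get
a relative percent abundance (``rel.abun``) computed against the per-sample
specimen total (recorded total where available, otherwise the within-sample
sum).  Binned codes map onto an ordered vocabulary (default
N < P < R < F < C < A < D -> 0..6); because letter meanings vary between
datasets ('A' can be absent or abundant), per-dataset vocabulary overrides
are honoured.  Stray letter codes inside an otherwise numeric sample are
treated as an inconsistently recorded trace presence and valued 0.01.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNIT_PA = "P/A"
UNIT_BINNED = "binned"
UNIT_COUNT = "count"
UNIT_RELATIVE = "relative abundance"
UNIT_PER_GRAM = "number per gram"
UNITS = (UNIT_PA, UNIT_BINNED, UNIT_COUNT, UNIT_RELATIVE, UNIT_PER_GRAM)

#: Value assigned to inconsistently recorded minority entries
#: (e.g. a 'P' inside a counted sample).
INCONSISTENT_VALUE = 0.01


class VocabularyError(ValueError):
    """A binned label has no code in the dataset's vocabulary."""


@dataclass(frozen=True)
class AbundanceVocabulary:
    """Ordered label sequence with numeric codes 0..k, strictly increasing."""

    labels: tuple[str, ...]
    codes: tuple[int, ...] = ()

    def __post_init__(self):
        codes = self.codes or tuple(range(len(self.labels)))
        object.__setattr__(self, "codes", codes)
        if len(codes) != len(self.labels):
            raise ValueError("labels and codes differ in length")
        if list(codes) != sorted(set(codes)) or (codes and codes[0] != 0):
            raise ValueError("codes must strictly increase from 0")

    def code(self, label: str) -> int:
        try:
            return self.codes[self.labels.index(label.strip().upper())]
        except ValueError:
            raise VocabularyError(
                f"label {label!r} not in vocabulary {self.labels}") from None

    def __contains__(self, label) -> bool:
        return isinstance(label, str) and \
            label.strip().upper() in self.labels


DEFAULT_VOCABULARY = AbundanceVocabulary(
    ("N", "P", "R", "F", "C", "A", "D"))


def load_vocabulary_overrides(path: str | Path
                              ) -> dict[str, AbundanceVocabulary]:
    """Per-dataset vocabularies from a CSV with columns db.ID, label, code."""
    df = pd.read_csv(path)
    out = {}
    for db_id, grp in df.groupby("db.ID"):
        grp = grp.sort_values("code")
        out[db_id] = AbundanceVocabulary(
            tuple(str(x).strip().upper() for x in grp["label"]),
            tuple(int(c) for c in grp["code"]))
    return out


def _as_float(v) -> float | None:
    try:
        return float(str(v).strip())
    except (TypeError, ValueError):
        return None


def classify_units(values, vocabulary: AbundanceVocabulary | None = None,
                   hint: str | None = None
                   ) -> tuple[str, np.ndarray]:
    """Classify one sample's raw abundance values into a unit type.

    Returns (units, inconsistent mask).  Mixed numeric/letter samples are
    classified by majority with the minority flagged inconsistent.  An
    explicit ``hint`` (e.g. "number per gram" from the source mapping) wins
    when values alone cannot distinguish counts from per-gram densities.
    Raises ValueError when nothing is classifiable.
    """
    vocabulary = vocabulary or DEFAULT_VOCABULARY
    vals = list(values)
    if not vals:
        raise ValueError("sample has no abundance values")
    numeric = np.array([_as_float(v) for v in vals], dtype=object)
    is_num = np.array([x is not None for x in numeric])
    is_letter = np.array([(not n) and (v in vocabulary)
                          for n, v in zip(is_num, vals)])
    if not (is_num.any() or is_letter.any()):
        raise ValueError(f"unclassifiable abundance values: {vals[:5]!r}")

    inconsistent = np.zeros(len(vals), dtype=bool)
    if is_letter.sum() > is_num.sum():
        units = UNIT_BINNED
        inconsistent = ~is_letter
        return units, inconsistent
    inconsistent = ~is_num
    nums = np.array([x for x in numeric if x is not None], dtype=float)
    if (nums < 0).any():
        raise ValueError("negative abundance values")
    if hint in UNITS:
        return hint, inconsistent
    if np.isin(nums, (0.0, 1.0)).all():
        return UNIT_PA, inconsistent
    if np.allclose(nums, np.round(nums)):
        return UNIT_COUNT, inconsistent
    return UNIT_RELATIVE, inconsistent


def to_numeric(value, units: str,
               vocabulary: AbundanceVocabulary | None = None,
               inconsistent: bool = False) -> float:
    """Numeric abundance for one raw value under a classified unit type.

    Binned letters map to their ordinal code; presence/absence to 1/0;
    counts, relative and per-gram values pass through numerically.  A value
    flagged inconsistent with its sample's units becomes 0.01.
    """
    vocabulary = vocabulary or DEFAULT_VOCABULARY
    if inconsistent:
        return INCONSISTENT_VALUE
    if units == UNIT_BINNED:
        return float(vocabulary.code(str(value)))
    x = _as_float(value)
    if x is None:
        raise VocabularyError(
            f"non-numeric value {value!r} in a {units} sample")
    if units == UNIT_PA:
        return 1.0 if x > 0 else 0.0
    return x


def harmonize_sample(sample: pd.DataFrame,
                     vocabulary: AbundanceVocabulary | None = None,
                     hint: str | None = None,
                     total_idd: float | None = None) -> pd.DataFrame:
    """Classify, convert and normalize one sample's records in place.

    Fills abundance, abun.units, total.IDd/num.ind/rel.abun (where the unit
    type admits proportions).
    """
    out = sample.copy()
    units, inconsistent = classify_units(out["orig.abundance"].tolist(),
                                         vocabulary, hint)
    out["abun.units"] = units
    out["abundance"] = [
        to_numeric(v, units, vocabulary, bool(f))
        for v, f in zip(out["orig.abundance"], inconsistent)]
    return relative_abundance(out, total_idd)


def relative_abundance(sample: pd.DataFrame,
                       total_idd: float | None = None) -> pd.DataFrame:
    """Per-sample specimen total and relative percent abundance.

    num.ind is the recorded total where supplied, else the sum of numeric
    abundances; rel.abun = 100 * abundance / num.ind for count and per-gram
    samples.  Relative-unit samples pass through (rel.abun = abundance).
    Binned and presence/absence samples keep rel.abun absent: ordinal codes
    are not proportions.
    """
    out = sample.copy()
    units = out["abun.units"].dropna().unique()
    unit = units[0] if len(units) else None
    if unit == UNIT_RELATIVE:
        out["rel.abun"] = out["abundance"]
        out["num.ind"] = total_idd if total_idd is not None else np.nan
        if total_idd is not None:
            out["total.IDd"] = total_idd
        return out
    if unit not in (UNIT_COUNT, UNIT_PER_GRAM):
        return out
    if total_idd is not None:
        out["total.IDd"] = total_idd
        num_ind = float(total_idd)
    else:
        num_ind = float(out["abundance"].sum())
    if num_ind == 0:
        if (out["abundance"] > 0).any():
            raise ValueError("zero specimen total with nonzero abundances")
        out["num.ind"] = 0.0
        return out
    out["num.ind"] = num_ind
    out["rel.abun"] = 100.0 * out["abundance"].astype(float) / num_ind
    return out


def split_zero_abundance(records: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(main set without zero-abundance records, full set keeping them).

    Zero-abundance rows indicate sampling effort and are retained only in
    the full dataset.
    """
    full = records.copy()
    main = records[records["abundance"] > 0].copy()
    return main.reset_index(drop=True), full.reset_index(drop=True)
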