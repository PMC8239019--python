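"""Validation summaries: richness, range completeness, coverage.

Richness is the count of distinct species per half-open time bin
[k*w, (k+1)*w) over the Cenozoic (0-66 Ma), computed on the trimmed record
set.  Completeness of a species' record is the fraction of time bins
overlapping its known stratigraphic range (treated as closed) that contain
at least one occurrence; 100% means the species is found in every bin of
its expected range.  The coverage grid counts records per (absolute
paleolatitude band x time bin) cell, folding hemispheres.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .qc import SpeciesRange

CENOZOIC_MAX_MA = 66.0


def _drop_trimmed(records: pd.DataFrame) -> pd.DataFrame:
    if "trim" in records.columns:
        return records[records["trim"] != "exc"]
    return records


def richness(records: pd.DataFrame, bin_width: float = 1.0) -> pd.Series:
    """Distinct-species count per time bin, excluding trim = "exc" records.

    Index is the bin lower edge; bins are half-open [k*w, (k+1)*w) from 0
    to the Cenozoic limit.
    """
    rec = _drop_trimmed(records).dropna(subset=["age", "species"])
    edges = np.arange(0.0, CENOZOIC_MAX_MA + bin_width, bin_width)
    lowers = edges[:-1]
    bin_idx = np.floor(rec["age"].to_numpy(dtype=float) / bin_width)
    counts = (pd.DataFrame({"bin": bin_idx, "species": rec["species"]})
              .groupby("bin")["species"].nunique())
    out = pd.Series(0, index=lowers, dtype=int, name="richness")
    for b, n in counts.items():
        lo = b * bin_width
        if 0 <= lo < CENOZOIC_MAX_MA:
            out.loc[lo] = int(n)
    return out


def expected_bins(rng: SpeciesRange, bin_width: float) -> np.ndarray:
    """Lower edges of the bins a species is expected in: every half-open
    bin overlapping its closed range [extinction, speciation].  A range
    endpoint exactly on a bin edge includes only the bin above that edge.
    """
    first = np.floor(rng.extinction / bin_width)
    q = rng.speciation / bin_width
    if np.isclose(q, np.round(q)) and rng.speciation > rng.extinction:
        # older endpoint exactly on an edge: the only overlap with the bin
        # above is the degenerate point, which is not an expected bin
        last = np.round(q) - 1
    else:
        last = np.floor(q)
    last = max(last, first)
    return np.arange(first, last + 1) * bin_width


@dataclass
class CompletenessSummary:
    per_species: pd.Series          # fraction in [0, 1] per species
    no_record_species: list[str]    # known range but zero records

    @property
    def median(self) -> float:
        return float(self.per_species.median())

    @property
    def mean(self) -> float:
        return float(self.per_species.mean())

    @property
    def n_complete(self) -> int:
        return int((self.per_species == 1.0).sum())

    @property
    def percent_complete(self) -> float:
        if len(self.per_species) == 0:
            return float("nan")
        return 100.0 * self.n_complete / len(self.per_species)


def completeness(records: pd.DataFrame,
                 ranges: Mapping[str, SpeciesRange],
                 bin_width: float = 1.0) -> CompletenessSummary:
    """Per-species fraction of expected bins occupied, with summaries.

    Species with a known range but no records are excluded from the
    summaries and reported separately.
    """
    rec = records.dropna(subset=["age", "species"])
    ages_by_species = {sp: grp["age"].to_numpy(dtype=float)
                       for sp, grp in rec.groupby("species")}
    values = {}
    missing = []
    for sp, rng in ranges.items():
        ages = ages_by_species.get(sp)
        if ages is None or len(ages) == 0:
            missing.append(sp)
            continue
        exp = expected_bins(rng, bin_width)
        occupied = np.unique(np.floor(ages / bin_width) * bin_width)
        n_occ = np.isin(exp, occupied).sum()
        values[sp] = n_occ / len(exp)
    per_species = pd.Series(values, dtype=float).sort_index()
    return CompletenessSummary(per_species, sorted(missing))


def coverage_grid(records: pd.DataFrame,
                  band_width: float = 30.0,
                  bin_width: float = 1.0) -> pd.DataFrame:
    """Record counts per (absolute-paleolatitude band x time bin) cell.

    Bands fold hemispheres (|pal.lat|), rows labelled "0-30", "30-60",
    "60-90" for the default width; columns are time-bin lower edges.  The
    grid total equals the record count (records with age and pal.lat).
    """
    rec = records.dropna(subset=["age", "pal.lat"])
    band_edges = np.arange(0.0, 90.0 + band_width, band_width)
    time_edges = np.arange(0.0, CENOZOIC_MAX_MA + bin_width, bin_width)
    lat = np.abs(rec["pal.lat"].to_numpy(dtype=float))
    age = rec["age"].to_numpy(dtype=float)
    H, _, _ = np.histogram2d(lat, age, bins=[band_edges, time_edges])
    # histogram2d closes the last bin on the right; fold the 90 edge in
    rows = [f"{band_edges[i]:g}-{band_edges[i+1]:g}"
            for i in range(len(band_edges) - 1)]
    return pd.DataFrame(H.astype(int), index=rows,
                        columns=time_edges[:-1])


def plot_richness(series: pd.Series, path) -> None:
    """Richness-through-time curve (age increases to the right)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.step(series.index, series.values, where="post")
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("species richness")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage(grid: pd.DataFrame, path) -> None:
    """Latitude x time heat grid of record counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(9, 3.5))
    im = ax.imshow(np.log1p(grid.to_numpy()), aspect="auto",
                   origin="lower", cmap="viridis",
                   extent=[grid.columns.min(),
                           grid.columns.max() + 1, 0, 90])
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("|paleolatitude|")
    ax.invert_xaxis()
    fig.colorbar(im, ax=ax, label="log(1 + records)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
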