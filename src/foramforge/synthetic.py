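"""Synthetic drill-core corpora with known truth.

Generates multi-source occurrence corpora that emulate the statistical
structure the pipeline assumes: piecewise-linear age-depth curves
(optionally broken by a hiatus), marker events observable at discrete
sample depths via the midpoint rule, species occurrences drawn from known
stratigraphic ranges with a detection probability, abundances rendered in
any of the supported encodings, reworked contaminant records injected at a
stated rate, and cross-source duplicate records with an exact ledger.
Every stochastic choice derives from the seed, so the same seed gives a
byte-identical corpus.

Event observation error is induced solely by sample spacing (the midpoint
rule), with optional Gaussian depth noise; this keeps the age-model
estimator's error sources separable in tests.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import TiePoint
from .qc import SpeciesRange, trim_tolerance

BINNED_LETTERS = ("P", "R", "F", "C", "A", "D")   # codes 1..6; 0 = absent


@dataclass(frozen=True)
class Hiatus:
    depth: float          # mbsf at which time is missing
    missing: float        # Ma of missing time, > 0

    def __post_init__(self):
        if self.missing <= 0:
            raise ValueError("hiatus missing-time must be > 0")


@dataclass(frozen=True)
class AgeDepthTruth:
    """Piecewise-linear true age-depth curve: sedimentation rates (m/Ma)
    per depth piece, with an optional hiatus adding a jump."""
    depth_span: float
    rates: tuple[float, ...] = (20.0,)
    breakpoints: tuple[float, ...] = ()          # depths where rate changes
    hiatus: Hiatus | None = None

    def __post_init__(self):
        if len(self.rates) != len(self.breakpoints) + 1:
            raise ValueError("need one rate per piece "
                             "(len(rates) == len(breakpoints) + 1)")
        if self.hiatus and not (0 < self.hiatus.depth < self.depth_span):
            raise ValueError("hiatus outside depth span")

    def age(self, depth) -> np.ndarray:
        """True age (Ma) at depth (mbsf); vectorized, non-decreasing."""
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        edges = (0.0, *self.breakpoints, self.depth_span)
        out = np.zeros_like(depth)
        base = 0.0
        for lo, hi, rate in zip(edges[:-1], edges[1:], self.rates):
            inside = np.clip(depth, lo, hi) - lo
            out += inside / rate
        if self.hiatus is not None:
            out += np.where(depth >= self.hiatus.depth,
                            self.hiatus.missing, 0.0)
        return out

    def depth_of_age(self, age: float) -> float | None:
        """Inverse mapping; None for ages inside the hiatus gap or beyond
        the core bottom."""
        if age < 0:
            return None
        grid = np.linspace(0.0, self.depth_span, 4001)
        ages = self.age(grid)
        if age > ages[-1]:
            return None
        if self.hiatus is not None:
            gap_lo = float(self.age(self.hiatus.depth - 1e-9)[0])
            gap_hi = gap_lo + self.hiatus.missing
            if gap_lo < age < gap_hi:
                return None
        return float(np.interp(age, ages, grid))

    @property
    def bottom_age(self) -> float:
        return float(self.age(self.depth_span)[0])


@dataclass(frozen=True)
class CoreParams:
    """Study conditions for one synthetic hole."""
    hole: str = "SYN1"
    plate: int = 101
    latitude: float = 10.0
    longitude: float = -30.0
    depth_span: float = 200.0            # m
    sample_spacing: float = 1.0          # m
    rates: tuple[float, ...] = (20.0,)   # m/Ma
    breakpoints: tuple[float, ...] = ()
    hiatus: Hiatus | None = None
    species: tuple[SpeciesRange, ...] = ()
    tie_spacing_ma: float = 0.5          # >= 1 event tie per Ma by default
    event_age_range: float = 0.0         # event age-interval width (Ma)
    magneto_every: int = 3               # every k-th event is a chron
    detection_prob: float = 1.0
    encoding: str = "count"              # count | binned | P/A | relative
    contamination_rate: float = 0.0
    contaminant_margin: float = 0.5      # Ma beyond the trim threshold
    depth_noise_sd: float = 0.0          # optional Gaussian tie-depth noise
    surface_holocene: bool = True


def default_species_pool(bottom_age: float, n_species: int = 8,
                         n_donors: int = 2) -> tuple[SpeciesRange, ...]:
    """A deterministic pool of ranges spanning the core's age window,
    plus ``n_donors`` much older "donor" taxa whose ranges lie entirely
    before the cored interval — these never occur legitimately and serve
    as reworked-contaminant sources."""
    pool = []
    for i in range(n_species):
        ext = (i % 3) * bottom_age / 6.0
        spec = ext + bottom_age * (0.35 + 0.6 * ((i * 37) % 10) / 10.0)
        spec = min(spec, bottom_age)
        if spec <= ext:
            spec = min(ext + bottom_age / 4.0, bottom_age)
        pool.append(SpeciesRange(f"Synthetica species{i + 1}",
                                 round(spec, 3), round(ext, 3)))
    for j in range(n_donors):
        ext = bottom_age + 8.0 + 2.0 * j
        pool.append(SpeciesRange(f"Vetusta donor{j + 1}",
                                 round(ext + 3.0, 3), round(ext, 3)))
    return tuple(pool)


@dataclass
class SyntheticCoreTruth:
    """Everything needed to check pipeline output against the generator."""
    hole: str
    plate: int
    latitude: float
    longitude: float
    curve: AgeDepthTruth
    events: pd.DataFrame                 # label, kind, age, true depth
    species: tuple[SpeciesRange, ...]
    contaminants: pd.DataFrame           # species, depth, sample age
    seed: int


def _snap_to_samples(depth: float, depths: np.ndarray) -> float | None:
    """Midpoint of the two samples bracketing a true event depth."""
    if depth <= depths[0] or depth > depths[-1]:
        return None
    i = int(np.searchsorted(depths, depth, side="left"))
    return 0.5 * (depths[i - 1] + depths[i])


def simulate_core(params: CoreParams, seed: int
                  ) -> tuple[pd.DataFrame, list[TiePoint],
                             SyntheticCoreTruth]:
    """One hole: raw occurrence table, observed tie points, and truth.

    The raw table has one row per present species per sample with columns
    ``species, abundance, depth`` plus truth-only columns ``contaminant``
    and ``true.age`` (ingestion mappings do not reference these).
    """
    rng = np.random.default_rng(seed)
    curve = AgeDepthTruth(params.depth_span, params.rates,
                          params.breakpoints, params.hiatus)
    species = params.species or default_species_pool(curve.bottom_age)

    depths = np.arange(params.sample_spacing, params.depth_span,
                       params.sample_spacing)
    ages = curve.age(depths)

    # --- marker events and their observed tie points
    event_ages = np.arange(params.tie_spacing_ma, curve.bottom_age,
                           params.tie_spacing_ma)
    ev_rows, ties = [], []
    if params.surface_holocene:
        ties.append(TiePoint(params.hole, 0.0, 0.0, 0.0, "seafloor",
                             "sediment surface"))
    for i, ev_age in enumerate(event_ages):
        true_depth = curve.depth_of_age(float(ev_age))
        if true_depth is None:        # age lost in the hiatus gap
            continue
        kind = ("magnetostratigraphic"
                if params.magneto_every and (i % params.magneto_every == 0)
                else "biostratigraphic")
        label = f"event{i + 1}"
        obs = _snap_to_samples(true_depth, depths)
        if obs is None:
            continue
        if params.depth_noise_sd > 0:
            obs = float(np.clip(obs + rng.normal(0, params.depth_noise_sd),
                                0.0, params.depth_span))
        ev_rows.append((label, kind, float(ev_age), true_depth))
        ties.append(TiePoint(params.hole, obs, float(ev_age),
                             params.event_age_range, kind, label))
    events = pd.DataFrame(ev_rows,
                          columns=["label", "kind", "age", "depth"])

    # --- species occurrences within ranges, plus contaminants
    rows = []
    contam_rows = []
    for depth, age in zip(depths, ages):
        used_contaminants: set[str] = set()
        for rng_sp in species:
            in_range = rng_sp.extinction <= age <= rng_sp.speciation
            if not in_range:
                continue
            if params.detection_prob < 1.0 and \
                    rng.random() >= params.detection_prob:
                continue
            rows.append((rng_sp.species,
                         _encode(params.encoding, rng), depth, 0, age))
            if params.contamination_rate > 0 and \
                    rng.random() < params.contamination_rate:
                bad = _pick_contaminant(species, age,
                                        params.contaminant_margin,
                                        used_contaminants)
                if bad is not None:
                    used_contaminants.add(bad.species)
                    rows.append((bad.species, _encode(params.encoding, rng),
                                 depth, 1, age))
                    contam_rows.append((bad.species, depth, age))
    raw = pd.DataFrame(rows, columns=["species", "abundance", "depth",
                                      "contaminant", "true.age"])
    # one row per species per sample: drop accidental repeats of a
    # contaminant species already present (cannot happen: contaminants are
    # out of range where residents are in range)
    truth = SyntheticCoreTruth(
        params.hole, params.plate, params.latitude, params.longitude,
        curve, events, species,
        pd.DataFrame(contam_rows, columns=["species", "depth", "age"]),
        seed)
    return raw, ties, truth


def _encode(encoding: str, rng: np.random.Generator):
    if encoding == "count":
        return int(rng.integers(1, 200))
    if encoding == "binned":
        return BINNED_LETTERS[int(rng.integers(0, len(BINNED_LETTERS)))]
    if encoding == "P/A":
        return 1
    if encoding == "relative":
        return float(np.round(rng.uniform(0.1, 50.0), 3))
    raise ValueError(f"unknown encoding {encoding!r}")


def _pick_contaminant(species: tuple[SpeciesRange, ...], age: float,
                      margin: float,
                      exclude: set[str] = frozenset()
                      ) -> SpeciesRange | None:
    """A species whose range excludes ``age`` by more than the trim
    threshold plus ``margin`` (so a correct pipeline must flag it)."""
    t = trim_tolerance(age) + margin
    for sp in species:
        if sp.species in exclude:
            continue
        if sp.extinction > age + t:          # reworked older taxon
            return sp
    for sp in species:
        if sp.species in exclude:
            continue
        if sp.speciation < age - t:          # anachronistically young taxon
            return sp
    return None


# --------------------------------------------------------------- corpora

#: Source dialects cycled across holes; the first is the highest-priority
#: primary source, the last holds injected duplicates.
SOURCE_DIALECTS = ("wide-count", "long-count", "long-binned", "long-pa")
DUPLICATE_SOURCE = "DUPSRC"


@dataclass
class SyntheticCorpus:
    """Per-source raw tables with their ingestion mappings, plus truth."""
    sources: dict[str, tuple[pd.DataFrame, dict]]
    truths: list[SyntheticCoreTruth]
    ties: dict[str, list[TiePoint]]
    duplicate_ledger: pd.DataFrame       # key fields of every injected dup
    seed: int

    def write(self, directory: str | Path) -> None:
        import yaml
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, (df, mapping) in self.sources.items():
            df.to_csv(directory / f"{name}.csv", index=False)
            with open(directory / f"{name}.yaml", "w") as fh:
                yaml.safe_dump(mapping, fh)


def _dialect_frame(raw: pd.DataFrame, dialect: str, source: str,
                   db_id: str, truth: SyntheticCoreTruth
                   ) -> tuple[pd.DataFrame, dict]:
    base_mapping = {
        "db_source": source, "db_id": db_id, "format": "long",
        "species": "species", "abundance": "abundance", "depth": "depth",
        "constants": {"latitude": truth.latitude,
                      "longitude": truth.longitude,
                      "hole": truth.hole},
    }
    if dialect == "wide-count":
        wide = (raw.pivot_table(index="depth", columns="species",
                                values="abundance", aggfunc="sum")
                .reset_index())
        wide.columns.name = None
        mapping = {"db_source": source, "db_id": db_id, "format": "wide",
                   "id_columns": ["depth"], "depth": "depth",
                   "constants": base_mapping["constants"]}
        return wide, mapping
    return raw[["species", "abundance", "depth"]].copy(), base_mapping


def simulate_corpus(n_holes: int = 4, overlap_fraction: float = 0.0,
                    seed: int = 0,
                    contamination_rate: float = 0.0,
                    base_params: CoreParams | None = None
                    ) -> SyntheticCorpus:
    """A multi-source corpus: ``n_holes`` holes in cycling source dialects,
    a fraction of records mirrored into a duplicate source with identical
    key fields (species, abundance, depth, coordinates), and an exact
    ledger of the injected duplicates."""
    rng = np.random.default_rng(seed)
    base = base_params or CoreParams()
    encodings = {"wide-count": "count", "long-count": "count",
                 "long-binned": "binned", "long-pa": "P/A"}
    sources: dict[str, tuple[pd.DataFrame, dict]] = {}
    truths, ties = [], {}
    all_long = []
    for h in range(n_holes):
        dialect = SOURCE_DIALECTS[h % len(SOURCE_DIALECTS)]
        params = replace(
            base,
            hole=f"SYN{h + 1}",
            latitude=float(np.round(-40 + 20 * h + 0.1 * h, 3)),
            longitude=float(np.round(-150 + 37 * h, 3)),
            encoding=encodings[dialect],
            contamination_rate=contamination_rate,
        )
        core_seed = int(rng.integers(0, 2 ** 31 - 1))
        raw, core_ties, truth = simulate_core(params, core_seed)
        source = f"SRC{h + 1}"
        frame, mapping = _dialect_frame(raw, dialect, source,
                                        f"ds{h + 1:03d}", truth)
        sources[source] = (frame, mapping)
        truths.append(truth)
        ties[truth.hole] = core_ties
        long = raw.copy()
        long["latitude"] = truth.latitude
        long["longitude"] = truth.longitude
        long["hole"] = truth.hole
        all_long.append(long)

    pool = pd.concat(all_long, ignore_index=True)
    n_dup = int(round(overlap_fraction * len(pool)))
    if n_dup > 0:
        picks = pool.iloc[np.sort(rng.choice(len(pool), size=n_dup,
                                             replace=False))]
        dup = picks[["species", "abundance", "depth",
                     "latitude", "longitude", "hole"]].copy()
        mapping = {"db_source": DUPLICATE_SOURCE, "db_id": "dup001",
                   "format": "long", "species": "species",
                   "abundance": "abundance", "depth": "depth",
                   "latitude": "latitude", "longitude": "longitude",
                   "hole": "hole"}
        sources[DUPLICATE_SOURCE] = (dup.reset_index(drop=True), mapping)
        ledger = dup.reset_index(drop=True)
    else:
        ledger = pd.DataFrame(columns=["species", "abundance", "depth",
                                       "latitude", "longitude", "hole"])
    return SyntheticCorpus(sources, truths, ties, ledger, seed)
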