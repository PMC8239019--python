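"""Age-depth modelling from tie points.

A hole's tie points (depth-age anchors from biostratigraphic and
magnetostratigraphic marker events, plus an optional 0 Ma seafloor tie) are
first split into segments wherever the age gap between depth-consecutive
ties exceeds 10% of the hole's tie-age range (a hiatus) or a declared
structural break (fault, slump) intervenes.  Within each segment up to five
estimators are fitted:

* ``zone``    - mean of the bounding tie ages per inter-tie interval, with
                the interval width as the error;
* ``magneto`` - the same, and an interpolation, restricted to
                magnetostratigraphic ties;
* ``interp``  - piecewise-linear interpolation between depth-consecutive
                ties, assuming constant sedimentation within each interval;
* ``model``   - a smooth trend of age on depth: an ordinary least-squares
                line when fewer than five ties are available, otherwise a
                penalized cubic B-spline whose smoothness is chosen by
                generalized cross-validation with the effective-degrees-of-
                freedom cost inflated by a factor of 1.1.

The estimator with the lowest root-mean-square deviation from the tie ages
(ties broken in the order interp > model > zone > magneto, overridable per
hole) supplies each sample's age and error; every estimator's prediction is
recorded alongside.  Samples outside the tie-point depth span of all
segments cannot be dated and are dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .chronology import TiePoint

HIATUS_FRACTION = 0.10       # age gap > fraction * hole age range -> hiatus
GCV_GAMMA = 1.1              # effective-df inflation in GCV
MAX_BASIS = 10               # spline basis size cap: min(10, n.pts - 1)
SELECTION_ORDER = ("interp", "model", "zone", "magneto")


# ---------------------------------------------------------------- estimators

class _Estimator:
    name: str = ""

    def predict(self, depths: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def error(self, depths: np.ndarray) -> np.ndarray:
        return np.full(np.shape(depths), np.nan)


@dataclass
class ZoneEstimator(_Estimator):
    """Mean of bounding tie ages per inter-tie interval.

    Intervals are half-open in depth, [d_i, d_{i+1}): a depth at a tie
    belongs to the interval below it (downcore).  Depths beyond the last
    tie fall back on that single bounding tie's age and its event width.
    """
    ties: list[TiePoint]
    name: str = "zone"

    def __post_init__(self):
        self._d = np.array([t.depth for t in self.ties])
        self._a = np.array([t.age for t in self.ties])
        self._r = np.array([t.age_range for t in self.ties])
        self._labels = [t.source for t in self.ties]

    def _interval(self, depth: float) -> tuple[int, int | None]:
        i = int(np.searchsorted(self._d, depth, side="right")) - 1
        i = max(i, 0)
        j = i + 1 if i + 1 < len(self._d) else None
        return i, j

    def table(self, depths: np.ndarray) -> pd.DataFrame:
        """zone label, zon.age, age.st, age.en, rng.age per depth."""
        rows = []
        for depth in np.atleast_1d(depths):
            i, j = self._interval(float(depth))
            if j is None:      # single bounding event
                rows.append((self._labels[i], self._a[i],
                             self._a[i] + self._r[i] / 2,
                             self._a[i] - self._r[i] / 2, self._r[i]))
            else:
                lo, hi = self._a[i], self._a[j]
                st, en = max(lo, hi), min(lo, hi)
                rows.append((f"{self._labels[i]}|{self._labels[j]}",
                             0.5 * (lo + hi), st, en, st - en))
        return pd.DataFrame(rows, columns=["zone", "zon.age", "age.st",
                                           "age.en", "rng.age"])

    def predict(self, depths: np.ndarray) -> np.ndarray:
        return self.table(depths)["zon.age"].to_numpy()

    def error(self, depths: np.ndarray) -> np.ndarray:
        return self.table(depths)["rng.age"].to_numpy()


@dataclass
class InterpEstimator(_Estimator):
    """Piecewise-linear age(depth) through the ties; the error is the
    larger of the bracketing ties' age ranges."""
    ties: list[TiePoint]
    name: str = "interp"

    def __post_init__(self):
        if len(self.ties) < 2:
            raise ValueError("interpolation needs >= 2 ties")
        self._d = np.array([t.depth for t in self.ties])
        self._a = np.array([t.age for t in self.ties])
        self._r = np.array([t.age_range for t in self.ties])

    def predict(self, depths: np.ndarray) -> np.ndarray:
        return np.interp(np.atleast_1d(depths).astype(float),
                         self._d, self._a)

    def error(self, depths: np.ndarray) -> np.ndarray:
        depths = np.atleast_1d(depths).astype(float)
        i = np.clip(np.searchsorted(self._d, depths, side="right") - 1,
                    0, len(self._d) - 2)
        return np.maximum(self._r[i], self._r[i + 1])


@dataclass
class TrendEstimator(_Estimator):
    """Smooth trend of age on depth: OLS line for n.pts < 5, else a
    penalized cubic B-spline with GCV-selected smoothness (1.1 df cost)."""
    ties: list[TiePoint]
    name: str = "model"
    kind: str = field(init=False)
    r2: float = field(init=False)
    n_pts: int = field(init=False)

    def __post_init__(self):
        x = np.array([t.depth for t in self.ties], dtype=float)
        y = np.array([t.age for t in self.ties], dtype=float)
        self.n_pts = len(x)
        if self.n_pts < 2 or np.ptp(x) == 0:
            raise ValueError("trend fit needs >= 2 ties at distinct depths")
        if self.n_pts < 5:
            self.kind = "linear"
            coef = np.polyfit(x, y, 1)
            self._predict = np.poly1d(coef)
            yhat = self._predict(x)
        else:
            self.kind = "smooth"
            self._predict = _fit_penalized_spline(
                x, y, k=min(MAX_BASIS, self.n_pts - 1))
            yhat = self._predict(x)
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(np.sum((y - yhat) ** 2))
        self.r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
        self._resid_rms = math.sqrt(ssr / self.n_pts)

    def predict(self, depths: np.ndarray) -> np.ndarray:
        return np.asarray(self._predict(np.atleast_1d(depths)
                                        .astype(float)))

    def error(self, depths: np.ndarray) -> np.ndarray:
        return np.full(np.shape(np.atleast_1d(depths)), self._resid_rms)


def _fit_penalized_spline(x: np.ndarray, y: np.ndarray, k: int,
                          gamma: float = GCV_GAMMA):
    """Penalized regression spline of y on x.

    Cubic B-spline basis of size ``k`` on uniformly spaced interior knots,
    second-difference penalty on the coefficients, smoothing parameter
    chosen on a log grid by minimizing GCV(lambda) =
    n * RSS / (n - gamma * edf)^2.  Returns a callable.
    """
    degree = 3
    k = max(k, degree + 1)
    n = len(x)
    lo, hi = float(x.min()), float(x.max())
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y

    best = (np.inf, None)
    for lam in np.concatenate([[0.0], np.logspace(-8, 10, 73)]):
        A = BtB + lam * P
        try:
            beta = np.linalg.solve(A, Bty)
            hat_trace = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:
            continue
        rss = float(np.sum((y - B @ beta) ** 2))
        denom = n - gamma * hat_trace
        gcv = np.inf if denom <= 0 else n * rss / denom ** 2
        if gcv < best[0]:
            best = (gcv, beta)
    if best[1] is None:
        raise np.linalg.LinAlgError("penalized spline fit failed")
    beta = best[1]
    spline = BSpline(t, beta, degree, extrapolate=True)
    return lambda d: spline(d)


# ------------------------------------------------------------- segmentation

@dataclass
class Segment:
    """Ties of one intact stratal interval and the estimators fitted to
    them."""
    index: int                       # 1-based
    ties: list[TiePoint]
    estimators: dict[str, _Estimator] = field(default_factory=dict)
    mag_zone: ZoneEstimator | None = None
    mag_interp: InterpEstimator | None = None
    selected: str = ""
    rmsd: dict[str, float] = field(default_factory=dict)

    @property
    def depth_span(self) -> tuple[float, float]:
        return self.ties[0].depth, self.ties[-1].depth

    @property
    def n_pts(self) -> int:
        return len(self.ties)


def segment_tiepoints(ties: Sequence[TiePoint],
                      declared_breaks: Sequence[float] = (),
                      hiatus_fraction: float = HIATUS_FRACTION
                      ) -> list[list[TiePoint]]:
    """Split depth-sorted ties at hiatuses and declared breaks.

    The hiatus rule: an age gap between depth-consecutive ties greater than
    ``hiatus_fraction`` of the hole's whole tie-age range (max - min tie
    age, before any split) starts a new segment.  Declared break depths
    (faults, slumps, from config) always split.
    """
    ties = sorted(ties, key=lambda t: (t.depth, t.age))
    if not ties:
        return []
    ages = [t.age for t in ties]
    age_range = max(ages) - min(ages)
    threshold = hiatus_fraction * age_range
    segments: list[list[TiePoint]] = [[ties[0]]]
    for prev, cur in zip(ties, ties[1:]):
        gap = abs(cur.age - prev.age)
        crosses_break = any(prev.depth < b <= cur.depth
                            for b in declared_breaks)
        if (age_range > 0 and gap > threshold) or crosses_break:
            segments.append([cur])
        else:
            segments[-1].append(cur)
    return segments


def _dedupe_magneto_preference(ties: list[TiePoint]) -> list[TiePoint]:
    # co-located bio + magneto ties: the magnetostratigraphic one wins
    by_depth: dict[float, TiePoint] = {}
    for t in ties:
        prev = by_depth.get(t.depth)
        if prev is None or (t.kind == "magnetostratigraphic"
                            and prev.kind != "magnetostratigraphic"):
            by_depth[t.depth] = t
    return [by_depth[d] for d in sorted(by_depth)]


def fit_segment(ties: list[TiePoint], index: int = 1) -> Segment:
    """Fit every available estimator to one segment's ties."""
    ties = _dedupe_magneto_preference(ties)
    seg = Segment(index=index, ties=ties)
    distinct_depths = len({t.depth for t in ties})
    seg.estimators["zone"] = ZoneEstimator(ties)
    if len(ties) >= 2 and distinct_depths >= 2:
        seg.estimators["interp"] = InterpEstimator(ties)
        seg.estimators["model"] = TrendEstimator(ties)
    mag = [t for t in ties if t.kind == "magnetostratigraphic"]
    if mag:
        seg.mag_zone = ZoneEstimator(mag)
        if len(mag) >= 2:
            seg.mag_interp = InterpEstimator(mag)
        seg.estimators["magneto"] = seg.mag_interp or seg.mag_zone
    return seg


def select_model(seg: Segment, override: str | None = None) -> str:
    """Choose the estimator with the lowest RMSD against the tie ages at
    the tie depths; RMSD ties break in the order interp > model > zone >
    magneto.  A per-hole override (standing in for manual confirmation)
    wins outright."""
    d = np.array([t.depth for t in seg.ties])
    a = np.array([t.age for t in seg.ties])
    for name, est in seg.estimators.items():
        seg.rmsd[name] = float(np.sqrt(np.mean(
            (est.predict(d) - a) ** 2)))
    if override is not None:
        if override not in seg.estimators:
            raise ValueError(f"override {override!r} not available "
                             f"(have {sorted(seg.estimators)})")
        seg.selected = override
        return override
    if not seg.estimators:
        raise ValueError("no estimator available for segment")
    seg.selected = min(
        seg.estimators,
        key=lambda n: (seg.rmsd[n], SELECTION_ORDER.index(n)))
    return seg.selected


@dataclass
class AgeDepthModel:
    """Fitted per-segment age estimators for one hole."""
    hole: str
    segments: list[Segment]

    @classmethod
    def fit(cls, hole: str, ties: Sequence[TiePoint],
            declared_breaks: Sequence[float] = (),
            override: str | None = None,
            hiatus_fraction: float = HIATUS_FRACTION) -> "AgeDepthModel":
        groups = segment_tiepoints(ties, declared_breaks, hiatus_fraction)
        segments = []
        for i, group in enumerate(groups, start=1):
            seg = fit_segment(group, index=i)
            if not seg.estimators:
                continue            # zero-tie segments carry no ages
            select_model(seg, override)
            segments.append(seg)
        if not segments:
            raise ValueError(f"hole {hole!r} is un-modellable: no segment "
                             "has a usable estimator")
        return cls(hole, segments)

    def segment_for(self, depth: float) -> Segment | None:
        for seg in self.segments:
            lo, hi = seg.depth_span
            if lo <= depth <= hi:
                return seg
        return None


def assign_ages(samples: pd.DataFrame, model: AgeDepthModel
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill age columns for every sample inside a segment's tie span.

    Samples already carrying a numeric age keep it (age.calc = "orig").
    Samples outside every segment's tie-point depth span cannot be dated
    and are dropped; the second frame lists them with the reason.
    """
    out = samples.copy()
    dropped = []
    keep = np.ones(len(out), dtype=bool)
    for pos, (idx, row) in enumerate(out.iterrows()):
        if not pd.isna(row.get("age")):
            out.loc[idx, "age.calc"] = "orig"
            continue
        depth = row["sample.depth"]
        seg = None if pd.isna(depth) else model.segment_for(float(depth))
        if seg is None:
            keep[pos] = False
            dropped.append((row.get("rowID"),
                            "outside age-model tie-point span"))
            continue
        d = np.array([float(depth)])
        out.loc[idx, "segment"] = seg.index

        zone = seg.estimators["zone"]
        zt = zone.table(d).iloc[0]
        for col in ("zone", "zon.age", "age.st", "age.en", "rng.age"):
            out.loc[idx, col] = zt[col]
        if "interp" in seg.estimators:
            est = seg.estimators["interp"]
            out.loc[idx, "int.age"] = est.predict(d)[0]
            out.loc[idx, "err.int.age"] = est.error(d)[0]
        if seg.mag_zone is not None:
            mt = seg.mag_zone.table(d).iloc[0]
            out.loc[idx, "mag.zone"] = mt["zone"]
            out.loc[idx, "mag.age"] = mt["zon.age"]
            out.loc[idx, "mag.age.st"] = mt["age.st"]
            out.loc[idx, "mag.age.en"] = mt["age.en"]
        if seg.mag_interp is not None:
            out.loc[idx, "int.mag.age"] = seg.mag_interp.predict(d)[0]
            out.loc[idx, "err.int.mag.age"] = seg.mag_interp.error(d)[0]
        if "model" in seg.estimators:
            trend = seg.estimators["model"]
            out.loc[idx, "mod.age"] = trend.predict(d)[0]
            out.loc[idx, "r2"] = trend.r2
            out.loc[idx, "n.pts"] = trend.n_pts
            out.loc[idx, "AM.type"] = trend.kind

        chosen = seg.estimators[seg.selected]
        out.loc[idx, "age"] = chosen.predict(d)[0]
        out.loc[idx, "age.err"] = chosen.error(d)[0]
        out.loc[idx, "age.calc"] = seg.selected
    kept = out[keep].reset_index(drop=True)
    return kept, pd.DataFrame(dropped, columns=["rowID", "reason"])


def plot_age_depth(model: AgeDepthModel, samples: pd.DataFrame | None,
                   path) -> None:
    """Diagnostic age-depth panel: ties plus every estimator overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 7))
    styles = {"zone": ":", "interp": "-", "model": "--", "magneto": "-."}
    for seg in model.segments:
        d = np.array([t.depth for t in seg.ties])
        a = np.array([t.age for t in seg.ties])
        ax.plot(a, d, "ko", ms=5, zorder=5)
        grid = np.linspace(d.min(), d.max(), 200)
        for name, est in seg.estimators.items():
            label = f"{name} (seg {seg.index})"
            ax.plot(est.predict(grid), grid, styles.get(name, "-"),
                    lw=1.2, label=label)
    ax.invert_yaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("depth (mbsf)")
    ax.legend(fontsize=7)
    ax.set_title(model.hole)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
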