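import numpy as np
import pandas as pd
import pytest

from foramforge import age_model as am
from foramforge import schema_io
from foramforge.chronology import TiePoint
from conftest import make_records


def tp(depth, age, rng=0.0, kind="biostratigraphic", hole="H"):
    return TiePoint(hole, depth, age, rng, kind, f"e@{depth}")


class TestSegmentation:
    def test_fourteen_percent_gap_splits(self):
        # range 50 Ma; consecutive ties 7 Ma apart (14%) -> split
        ties = [tp(0, 0), tp(10, 20), tp(20, 27), tp(30, 50)]
        segs = am.segment_tiepoints(ties)
        assert [len(s) for s in segs] == [1, 1, 1, 1]  # 40%,14%,46% gaps

    def test_eight_percent_gap_does_not_split(self):
        ties = [tp(0, 0), tp(10, 23), tp(20, 27), tp(30, 50)]
        segs = am.segment_tiepoints(ties)
        assert [len(s) for s in segs] == [1, 2, 1]     # only 46% gaps split

    def test_declared_break_always_splits(self):
        # gaps are 9% of the range, below the hiatus threshold; only the
        # declared structural break splits
        ties = [tp(10 * k, 0.1 * k) for k in range(12)]
        assert len(am.segment_tiepoints(ties)) == 1
        segs = am.segment_tiepoints(ties, declared_breaks=[55.0])
        assert [len(s) for s in segs] == [6, 6]

    def test_splitting_invariant_to_interior_ties(self):
        base = [tp(0, 0), tp(10, 1), tp(20, 2), tp(30, 10)]
        with_extra = base + [tp(5, 0.5), tp(15, 1.5)]
        n_base = len(am.segment_tiepoints(base))
        n_extra = len(am.segment_tiepoints(with_extra))
        assert n_base == n_extra == 2


class TestZoneEstimator:
    def test_mean_and_width_of_bounding_ties(self):
        est = am.ZoneEstimator([tp(10, 5.0), tp(20, 6.0)])
        row = est.table(np.array([15.0])).iloc[0]
        assert row["zon.age"] == 5.5
        assert row["rng.age"] == 1.0
        assert (row["age.st"], row["age.en"]) == (6.0, 5.0)

    def test_single_bounding_event_uses_its_mean_and_width(self):
        est = am.ZoneEstimator([tp(10, 5.0, rng=0.4)])
        row = est.table(np.array([12.0])).iloc[0]
        assert row["zon.age"] == 5.0
        assert row["rng.age"] == 0.4


class TestInterpEstimator:
    def test_linear_midpoint(self):
        est = am.InterpEstimator([tp(10, 1.0), tp(20, 2.0)])
        assert est.predict(np.array([15.0]))[0] == pytest.approx(1.5)

    def test_exact_at_tie_depths(self):
        est = am.InterpEstimator([tp(10, 1.0), tp(20, 2.0), tp(35, 2.6)])
        assert est.predict(np.array([20.0]))[0] == 2.0

    def test_error_is_larger_bracketing_range(self):
        est = am.InterpEstimator([tp(10, 1.0, rng=0.2),
                                  tp(20, 2.0, rng=0.6)])
        assert est.error(np.array([15.0]))[0] == 0.6

    def test_monotone_when_tie_ages_are(self):
        ties = [tp(d, a) for d, a in [(0, 0), (10, 1), (20, 1.2),
                                      (30, 4), (40, 4.5)]]
        est = am.InterpEstimator(ties)
        grid = np.linspace(0, 40, 200)
        assert (np.diff(est.predict(grid)) >= -1e-12).all()


class TestTrendEstimator:
    def test_three_ties_use_linear_model(self):
        est = am.TrendEstimator([tp(0, 0), tp(10, 1), tp(20, 2)])
        assert est.kind == "linear"
        assert est.n_pts == 3
        assert est.r2 == pytest.approx(1.0)

    def test_five_collinear_ties_smooth_reproduces_line(self):
        ties = [tp(d, d / 10.0) for d in (0, 10, 20, 30, 40)]
        est = am.TrendEstimator(ties)
        assert est.kind == "smooth"
        assert est.r2 == pytest.approx(1.0, abs=1e-6)
        assert est.predict(np.array([25.0]))[0] == pytest.approx(2.5,
                                                                 abs=1e-6)

    def test_two_rate_core_recovered_within_quarter_ma(self):
        # sedimentation 10 m/Ma above 60 m, 40 m/Ma below; 12 ties
        depths = np.linspace(0, 120, 12)
        truth = np.where(depths <= 60, depths / 10.0,
                         6.0 + (depths - 60) / 40.0)
        est = am.TrendEstimator([tp(float(d), float(a))
                                 for d, a in zip(depths, truth)])
        assert est.kind == "smooth"
        assert np.max(np.abs(est.predict(depths) - truth)) < 0.25

    def test_smooth_close_to_independent_gcv_spline(self):
        # cross-check against scipy's GCV smoothing spline on a noisy
        # monotone trend; both should land near the underlying curve
        from scipy.interpolate import make_smoothing_spline
        rng = np.random.default_rng(3)
        x = np.linspace(0, 100, 25)
        y = x / 20.0 + 0.3 * np.sin(x / 15.0) + rng.normal(0, 0.05, 25)
        est = am.TrendEstimator([tp(float(a), float(b))
                                 for a, b in zip(x, y)])
        oracle = make_smoothing_spline(x, y)
        assert np.max(np.abs(est.predict(x) - oracle(x))) < 0.15

    def test_all_ties_at_one_depth_unavailable(self):
        with pytest.raises(ValueError):
            am.TrendEstimator([tp(5, 1), tp(5, 2)])


class TestSelection:
    def test_noiseless_linear_core_prefers_interp(self):
        seg = am.fit_segment([tp(d, d / 20.0) for d in
                              np.arange(0, 101, 10)])
        assert am.select_model(seg) == "interp"
        assert seg.rmsd["interp"] == 0.0

    def test_override_wins_regardless_of_rmsd(self):
        seg = am.fit_segment([tp(d, d / 20.0) for d in
                              np.arange(0, 101, 10)])
        assert am.select_model(seg, override="model") == "model"

    def test_magneto_variant_computed_in_parallel(self):
        ties = [tp(0, 0), tp(10, 1, kind="magnetostratigraphic"),
                tp(20, 2), tp(30, 3, kind="magnetostratigraphic")]
        seg = am.fit_segment(ties)
        assert seg.mag_interp is not None
        assert "magneto" in seg.estimators

    def test_no_magneto_ties_no_magneto_variant(self):
        seg = am.fit_segment([tp(0, 0), tp(10, 1)])
        assert seg.mag_zone is None and "magneto" not in seg.estimators


def _samples(depths):
    return make_records([{"rowID": f"r{i}", "sample.depth": float(d),
                          "species": "S x", "abundance": 1.0}
                         for i, d in enumerate(depths)])


class TestAssignAges:
    def test_sample_outside_tie_span_dropped(self, linear_ties):
        model = am.AgeDepthModel.fit("H1", linear_ties)
        kept, dropped = am.assign_ages(_samples([50.0, 150.0]), model)
        assert len(kept) == 1
        assert dropped.iloc[0]["reason"] == \
            "outside age-model tie-point span"

    def test_sample_at_tie_depth_gets_tie_age_and_range(self, linear_ties):
        model = am.AgeDepthModel.fit("H1", linear_ties)
        kept, _ = am.assign_ages(_samples([40.0]), model)
        assert kept.loc[0, "age.calc"] == "interp"
        assert kept.loc[0, "age"] == pytest.approx(2.0)
        assert kept.loc[0, "age.err"] == pytest.approx(0.2)

    def test_existing_numeric_age_kept_as_orig(self, linear_ties):
        model = am.AgeDepthModel.fit("H1", linear_ties)
        rec = _samples([40.0])
        rec.loc[0, "age"] = 1.23
        kept, _ = am.assign_ages(rec, model)
        assert kept.loc[0, "age"] == 1.23
        assert kept.loc[0, "age.calc"] == "orig"

    def test_assigned_age_within_segment_tie_ages(self, linear_ties):
        model = am.AgeDepthModel.fit("H1", linear_ties)
        kept, _ = am.assign_ages(_samples(np.linspace(0, 100, 37)), model)
        ages = [t.age for t in model.segments[0].ties]
        assert (kept["int.age"] >= min(ages) - 1e-12).all()
        assert (kept["int.age"] <= max(ages) + 1e-12).all()
        assert (kept["zon.age"] >= min(ages) - 1e-12).all()
        assert (kept["zon.age"] <= max(ages) + 1e-12).all()

    def test_hiatus_core_gets_segment_indices(self):
        ties = [tp(d, d / 20.0) for d in np.arange(0, 51, 10)]
        ties += [tp(d, d / 20.0 + 4.0) for d in np.arange(60, 111, 10)]
        model = am.AgeDepthModel.fit("H", ties)  # 4 Ma jump on ~9 Ma range
        assert len(model.segments) == 2
        kept, _ = am.assign_ages(_samples([25.0, 85.0]), model)
        assert kept["segment"].tolist() == [1.0, 2.0]


class TestPlot:
    def test_age_depth_panel_written(self, tmp_path, linear_ties):
        model = am.AgeDepthModel.fit("H1", linear_ties)
        out = tmp_path / "panel.png"
        am.plot_age_depth(model, None, out)
        assert out.stat().st_size > 0
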