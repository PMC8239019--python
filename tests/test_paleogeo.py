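import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation, Slerp

from foramforge import paleogeo as pg
from conftest import make_records

ROT_FILE = """\
701  0.0  90.0   0.0   0.0  001 ! anchor-fixed plate, identity at present
701 10.0  30.0  40.0  10.0  001 ! total rotation at 10 Ma
701 20.0  30.0  40.0  20.0  001 ! same axis, doubled angle
801  0.0  90.0   0.0   0.0  701 ! plate moving relative to 701
801 20.0  10.0  50.0   8.0  701 !
999  5.0   0.0   0.0   1.0  001 ! commented-out line
"""


@pytest.fixture
def rot_path(tmp_path):
    path = tmp_path / "model.rot"
    path.write_text(ROT_FILE)
    return path


class TestParseRotationFile:
    def test_zero_angle_line_is_identity(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rot = table.total_rotation(701, 0.0)
        assert rot.angle == 0.0

    def test_two_plate_chain_parses_into_circuit(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        assert table.plates == [701, 801]
        assert table.total_rotation(801, 20.0) is not None

    def test_commented_999_lines_skipped(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        assert 999 not in table.plates

    def test_decreasing_ages_fatal(self, tmp_path):
        path = tmp_path / "bad.rot"
        path.write_text("701 10.0 30 40 10 001 !\n701 5.0 30 40 5 001 !\n")
        with pytest.raises(pg.RotationFileError, match="increasing"):
            pg.parse_rotation_file(path)

    def test_unknown_fixed_plate_fatal_naming_it(self, tmp_path):
        path = tmp_path / "orphan.rot"
        path.write_text("801 10.0 30 40 10 555 !\n")
        with pytest.raises(pg.RotationFileError, match="555"):
            pg.parse_rotation_file(path)


class TestTotalRotation:
    def test_age_zero_identity_for_every_plate(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        for plate in table.plates:
            assert table.total_rotation(plate, 0.0).angle == 0.0

    def test_age_at_node_returns_entry_through_circuit(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rot = table.total_rotation(701, 10.0)
        assert (rot.pole_lat, rot.pole_lon, rot.angle) == \
            pytest.approx((30.0, 40.0, 10.0))

    def test_shared_axis_midway_age_gives_mean_angle(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rot = table.total_rotation(701, 15.0)
        assert (rot.pole_lat, rot.pole_lon, rot.angle) == \
            pytest.approx((30.0, 40.0, 15.0))

    def test_interpolation_matches_slerp_oracle(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        r1 = pg.FiniteRotation(30, 40, 10).as_rotation()
        r2 = pg.FiniteRotation(30, 40, 20).as_rotation()
        slerp = Slerp([10.0, 20.0], Rotation.concatenate([r1, r2]))
        for age in (11.0, 14.5, 19.0):
            ours = table.total_rotation(701, age).as_rotation()
            oracle = slerp(age)
            assert (ours.inv() * oracle).magnitude() < 1e-12

    def test_age_outside_span_returns_none(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        assert table.total_rotation(701, 25.0) is None

    def test_continuity_between_nodes(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        ages = np.linspace(0.1, 19.9, 80)
        rots = [table.total_rotation(701, a).as_rotation() for a in ages]
        steps = [np.degrees((u.inv() * v).magnitude())
                 for u, v in zip(rots, rots[1:])]
        assert max(steps) < 1.0     # 20 deg over 20 Ma, 0.25 Ma steps


class TestRotatePoint:
    def test_identity_leaves_coordinates(self):
        lat, lon = pg.rotate_point(12.3, -45.6,
                                   pg.FiniteRotation(90, 0, 0))
        assert (lat, lon) == pytest.approx((12.3, -45.6))

    def test_north_pole_thirty_degrees_moves_equator_east(self):
        lat, lon = pg.rotate_point(0.0, 0.0,
                                   pg.FiniteRotation(90.0, 0.0, 30.0))
        assert lat == pytest.approx(0.0, abs=1e-12)
        assert lon == pytest.approx(30.0)

    def test_rotation_then_inverse_recovers_point(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            rot = pg.FiniteRotation(rng.uniform(-90, 90),
                                    rng.uniform(-180, 180),
                                    rng.uniform(-180, 180))
            p = (rng.uniform(-90, 90), rng.uniform(-179, 179))
            mid = pg.rotate_point(*p, rot)
            back = pg.rotate_point(*mid, rot.inverse())
            assert back[0] == pytest.approx(p[0], abs=1e-9)
            assert back[1] == pytest.approx(p[1], abs=1e-9)

    def test_output_normalized(self):
        lat, lon = pg.rotate_point(0.0, 170.0,
                                   pg.FiniteRotation(90.0, 0.0, 30.0))
        assert -90 <= lat <= 90 and -180 < lon <= 180
        assert lon == pytest.approx(-160.0)


class TestPaleocoordinates:
    def _records(self, ages, hole="S:H1"):
        return make_records([
            {"rowID": f"r{i}", "holeID": hole, "latitude": 0.0,
             "longitude": 0.0, "age": a} for i, a in enumerate(ages)])

    def test_modern_samples_keep_modern_coordinates(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rec, log = pg.paleocoordinates(self._records([0.0]), table,
                                       {"S:H1": 701})
        assert rec.loc[0, "pal.lat"] == 0.0
        assert rec.loc[0, "pal.long"] == 0.0
        assert log.empty

    def test_different_ages_give_different_positions(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rec, _ = pg.paleocoordinates(self._records([5.0, 15.0]), table,
                                     {"S:H1": 701})
        assert rec.loc[0, "pal.long"] != rec.loc[1, "pal.long"]

    def test_uncovered_records_flagged_matching_construction(self,
                                                             rot_path):
        # 3 of 5 ages inside the covered span -> exactly 3 assigned
        table = pg.parse_rotation_file(rot_path)
        rec, log = pg.paleocoordinates(
            self._records([5.0, 10.0, 15.0, 25.0, 30.0]), table,
            {"S:H1": 701})
        assert rec["pal.lat"].notna().sum() == 3
        assert len(log) == 2

    def test_missing_plate_assignment_logged(self, rot_path):
        table = pg.parse_rotation_file(rot_path)
        rec, log = pg.paleocoordinates(self._records([5.0]), table, {})
        assert rec["pal.lat"].isna().all()
        assert log.iloc[0]["reason"] == "no plate assignment"


class TestRotationAlgebra:
    def test_compose_inverse_identity_and_distance_preservation(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            rot = pg.FiniteRotation(rng.uniform(-90, 90),
                                    rng.uniform(-180, 180),
                                    rng.uniform(-180, 180)).as_rotation()
            assert (rot * rot.inv()).magnitude() < 1e-12
            p = pg._unit_vector(rng.uniform(-90, 90),
                                rng.uniform(-180, 180))
            q = pg._unit_vector(rng.uniform(-90, 90),
                                rng.uniform(-180, 180))
            before = np.degrees(np.arccos(np.clip(p @ q, -1, 1)))
            after = np.degrees(np.arccos(np.clip(
                rot.apply(p) @ rot.apply(q), -1, 1)))
            assert abs(before - after) < 1e-9
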