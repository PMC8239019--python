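"""Paleocoordinates from finite (Euler-pole) rotations.

A plate-motion model is a table of total reconstruction rotations: for each
moving plate, an age-ordered list of (pole latitude, pole longitude, angle)
relative to a fixed plate, forming a circuit to the anchor plate (id 0 or
1).  This module parses the standard whitespace-delimited ".rot" dialect,
interpolates total rotations in stage-rotation space (equivalent to
spherical linear interpolation — never naive pole/angle averaging, which is
wrong for large angles), composes rotations through the plate circuit, and
rotates modern site coordinates to their deposition-age positions.

Sign convention: a positive angle is counter-clockwise looking down the
pole axis from outside the sphere (the right-hand rule, as in the ".rot"
format).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

ANCHOR_PLATES = frozenset({0, 1})


class RotationFileError(ValueError):
    """Malformed rotation file (non-monotone ages, broken circuit...)."""


@dataclass(frozen=True)
class FiniteRotation:
    """An Euler-pole rotation at an age: (pole lat, pole lon, angle) moving
    one plate relative to a fixed plate.  Composable and invertible."""
    pole_lat: float
    pole_lon: float
    angle: float                  # degrees, right-hand rule
    age: float = 0.0
    moving: int = 0
    fixed: int = 0

    def as_rotation(self) -> Rotation:
        axis = _unit_vector(self.pole_lat, self.pole_lon)
        return Rotation.from_rotvec(np.deg2rad(self.angle) * axis)

    def inverse(self) -> "FiniteRotation":
        return FiniteRotation(self.pole_lat, self.pole_lon, -self.angle,
                              self.age, self.fixed, self.moving)

    @classmethod
    def from_rotation(cls, rot: Rotation, age: float = 0.0,
                      moving: int = 0, fixed: int = 0) -> "FiniteRotation":
        rv = rot.as_rotvec()
        angle = np.rad2deg(np.linalg.norm(rv))
        if angle == 0:
            return cls(90.0, 0.0, 0.0, age, moving, fixed)
        axis = rv / np.linalg.norm(rv)
        lat = np.rad2deg(np.arcsin(np.clip(axis[2], -1, 1)))
        lon = np.rad2deg(np.arctan2(axis[1], axis[0]))
        return cls(float(lat), float(lon), float(angle), age, moving, fixed)


def _unit_vector(lat: float, lon: float) -> np.ndarray:
    la, lo = np.deg2rad(lat), np.deg2rad(lon)
    return np.array([np.cos(la) * np.cos(lo),
                     np.cos(la) * np.sin(lo),
                     np.sin(la)])


def _to_lat_lon(v: np.ndarray) -> tuple[float, float]:
    lat = np.rad2deg(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(v[1], v[0]))
    if lon <= -180.0:
        lon += 360.0
    return float(lat), float(lon)


class RotationTable:
    """Per-plate, age-ordered total rotations with circuit closure to the
    anchor plate."""

    def __init__(self, entries: pd.DataFrame):
        need = {"moving", "age", "pole_lat", "pole_lon", "angle", "fixed"}
        if not need <= set(entries.columns):
            raise ValueError(f"rotation table needs columns {need}")
        self._by_plate: dict[int, pd.DataFrame] = {}
        for plate, grp in entries.groupby("moving"):
            grp = grp.reset_index(drop=True)
            ages = grp["age"].to_numpy(dtype=float)
            if not (np.diff(ages) > 0).all():
                raise RotationFileError(
                    f"plate {plate}: ages not strictly increasing")
            self._by_plate[int(plate)] = grp
        self._verify_circuits()

    def _verify_circuits(self) -> None:
        for plate in self._by_plate:
            seen = {plate}
            cur = plate
            while cur not in ANCHOR_PLATES:
                fixed = {int(f) for f in self._by_plate[cur]["fixed"]}
                if len(fixed) != 1:
                    # plates may change fixed plate with age; accept but
                    # follow the youngest entry's fixed plate for closure
                    fixed = {int(self._by_plate[cur]["fixed"].iloc[0])}
                nxt = fixed.pop()
                if nxt in ANCHOR_PLATES:
                    break
                if nxt not in self._by_plate:
                    raise RotationFileError(
                        f"circuit of plate {plate}: unknown fixed plate "
                        f"{nxt}")
                if nxt in seen:
                    raise RotationFileError(
                        f"circuit of plate {plate}: cycle at plate {nxt}")
                seen.add(nxt)
                cur = nxt

    @property
    def plates(self) -> list[int]:
        return sorted(self._by_plate)

    def covered_span(self, plate: int) -> tuple[float, float]:
        grp = self._by_plate[plate]
        return float(grp["age"].min()), float(grp["age"].max())

    def _plate_rotation(self, plate: int, age: float) -> Rotation | None:
        """Interpolated total rotation of ``plate`` relative to its fixed
        plate at ``age``; None when the age is outside the covered span."""
        grp = self._by_plate.get(plate)
        if grp is None:
            return None
        ages = grp["age"].to_numpy(dtype=float)
        lo, hi = ages[0], ages[-1]
        if age < lo - 1e-12 or age > hi + 1e-12:
            if age == 0.0:
                return Rotation.identity()
            return None
        i = int(np.searchsorted(ages, age, side="right")) - 1
        i = min(max(i, 0), len(ages) - 1)
        row = grp.iloc[i]
        r1 = FiniteRotation(row["pole_lat"], row["pole_lon"],
                            row["angle"]).as_rotation()
        if abs(age - ages[i]) <= 1e-12 or i == len(ages) - 1:
            return r1
        nxt = grp.iloc[i + 1]
        r2 = FiniteRotation(nxt["pole_lat"], nxt["pole_lon"],
                            nxt["angle"]).as_rotation()
        frac = (age - ages[i]) / (ages[i + 1] - ages[i])
        stage = r1.inv() * r2
        return r1 * Rotation.from_rotvec(frac * stage.as_rotvec())

    def _fixed_plate(self, plate: int) -> int:
        return int(self._by_plate[plate]["fixed"].iloc[0])

    def total_rotation(self, plate: int, age: float
                       ) -> FiniteRotation | None:
        """Total rotation of ``plate`` relative to the anchor at ``age``,
        composed through the plate circuit.  None when the model does not
        cover this plate/age (such sites are skipped and logged upstream)."""
        if age == 0.0:
            return FiniteRotation(90.0, 0.0, 0.0, 0.0, plate, 0)
        if plate in ANCHOR_PLATES:
            return FiniteRotation(90.0, 0.0, 0.0, age, plate, 0)
        total = Rotation.identity()
        cur = plate
        while cur not in ANCHOR_PLATES:
            r = self._plate_rotation(cur, age)
            if r is None:
                return None
            total = r * total       # position in the next frame up
            cur = self._fixed_plate(cur)
        return FiniteRotation.from_rotation(total, age, plate, 0)


def parse_rotation_file(path: str | Path) -> RotationTable:
    """Parse the whitespace-delimited ".rot" dialect.

    Each line: moving plate, age, pole lat, pole lon, angle, fixed plate,
    optional "!" comment.  Lines that are blank, start with a comment
    marker, or use the 999 commented-out moving-plate id are skipped.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("!", 1)[0].strip()
            if not body or body.startswith("#"):
                continue
            parts = body.split()
            if len(parts) < 6:
                raise RotationFileError(
                    f"line {lineno}: expected 6 fields, got {len(parts)}")
            moving = int(parts[0])
            if moving == 999:
                continue
            rows.append({
                "moving": moving,
                "age": float(parts[1]),
                "pole_lat": float(parts[2]),
                "pole_lon": float(parts[3]),
                "angle": float(parts[4]),
                "fixed": int(parts[5]),
            })
    if not rows:
        raise RotationFileError(f"no rotation entries in {path!r}")
    return RotationTable(pd.DataFrame(rows))


def rotate_point(latitude: float, longitude: float,
                 rotation: FiniteRotation | Rotation
                 ) -> tuple[float, float]:
    """Rotate a point on the unit sphere; output normalized to
    lat in [-90, 90], lon in (-180, 180]."""
    rot = rotation.as_rotation() if isinstance(rotation, FiniteRotation) \
        else rotation
    return _to_lat_lon(rot.apply(_unit_vector(latitude, longitude)))


def paleocoordinates(records: pd.DataFrame, table: RotationTable,
                     plate_assignments: Mapping[str, int]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill pal.lat / pal.long per record by rotating the site back to its
    deposition-age position.

    Modern samples (age 0) keep their modern coordinates.  Records whose
    hole has no plate id, or whose age the model does not cover, stay
    unassigned (they later fail the crucial-column filter); the log frame
    lists them.
    """
    out = records.copy()
    log = []
    cache: dict[tuple[int, float], FiniteRotation | None] = {}
    for idx, row in out.iterrows():
        age = row["age"]
        lat, lon = row["latitude"], row["longitude"]
        if pd.isna(age) or pd.isna(lat) or pd.isna(lon):
            log.append((row.get("rowID"), "missing age or coordinates"))
            continue
        if age == 0.0:
            out.loc[idx, "pal.lat"] = lat
            out.loc[idx, "pal.long"] = lon
            continue
        plate = plate_assignments.get(row["holeID"])
        if plate is None:
            log.append((row.get("rowID"), "no plate assignment"))
            continue
        key = (plate, round(float(age), 6))
        if key not in cache:
            cache[key] = table.total_rotation(plate, float(age))
        rot = cache[key]
        if rot is None:
            log.append((row.get("rowID"),
                        f"age {age} outside rotation model span for "
                        f"plate {plate}"))
            continue
        plat, plon = rotate_point(float(lat), float(lon), rot)
        out.loc[idx, "pal.lat"] = plat
        out.loc[idx, "pal.long"] = plon
    return out, pd.DataFrame(log, columns=["rowID", "reason"])
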