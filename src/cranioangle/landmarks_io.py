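"""Landmark frame-sequence containers and CSV/JSON I/O.

A scan frame is a set of named anatomical landmarks in millimetres:
sellion, promentale, subnasale, left/right tragion, left/right ectocanthus,
left/right acromion (required) and left/right infraorbitale (optional).
Sequences are ordered, timestamped collections of frames at a nominal frame
rate, matching a 10 fps / 20 s surface-scan capture.

Coordinate convention (shared package-wide): right-handed, +x = subject's
right, +y = up, +z = anterior. Units are always millimetres; there is no
unit auto-detection.

The long-form CSV dialect is ``frame_id,time_s,landmark,x_mm,y_mm,z_mm``
(one landmark per row); the JSON dialect is a list of
``{"frame_id": ..., "time_s": ..., "points": {name: [x, y, z]}}`` objects.
Both round-trip losslessly at full float precision.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "REQUIRED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "LandmarkSet",
    "FrameSequence",
    "canonical_landmark_name",
    "read_frames",
    "write_frames",
    "template_head",
    "write_angles_csv",
]

REQUIRED_LANDMARKS: tuple[str, ...] = (
    "sellion",
    "promentale",
    "subnasale",
    "tragion_left",
    "tragion_right",
    "ectocanthus_left",
    "ectocanthus_right",
    "acromion_left",
    "acromion_right",
)

OPTIONAL_LANDMARKS: tuple[str, ...] = ("infraorbitale_left", "infraorbitale_right")

#: Accepted spelling variants, mapped to canonical tokens. The clinical
#: literature uses both "subnasal" and "subnasale" for the same point.
_ALIASES: dict[str, str] = {
    "subnasal": "subnasale",
}

_MIN_ACROMION_SEP_MM = 1.0


def canonical_landmark_name(name: str) -> str:
    """Normalize a landmark name: lowercase, spaces/hyphens to underscores,
    known spelling aliases resolved. Unknown names pass through normalized."""
    token = name.strip().lower().replace(" ", "_").replace("-", "_")
    return _ALIASES.get(token, token)


@dataclass
class LandmarkSet:
    """Named 3D landmarks of one scan frame (mm)."""

    points: dict[str, np.ndarray]
    frame_id: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.points = {
            canonical_landmark_name(k): np.asarray(v, dtype=float)
            for k, v in self.points.items()
        }

    def validate(self) -> None:
        for name in REQUIRED_LANDMARKS:
            if name not in self.points:
                raise SchemaError(
                    f"frame {self.frame_id}: required landmark {name!r} is missing"
                )
        for name, p in self.points.items():
            if p.shape != (3,):
                raise SchemaError(
                    f"frame {self.frame_id}: landmark {name!r} is not a 3-vector"
                )
            if not np.all(np.isfinite(p)):
                raise SchemaError(
                    f"frame {self.frame_id}: landmark {name!r} has non-finite coordinates"
                )
        sep = float(np.linalg.norm(self.points["acromion_right"] - self.points["acromion_left"]))
        if sep <= _MIN_ACROMION_SEP_MM:
            raise SchemaError(
                f"frame {self.frame_id}: acromions {sep:.3g} mm apart "
                f"(must exceed {_MIN_ACROMION_SEP_MM} mm)"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[canonical_landmark_name(name)]

    def midpoint(self, a: str, b: str) -> np.ndarray:
        return 0.5 * (self[a] + self[b])

    @property
    def midtragion(self) -> np.ndarray:
        return self.midpoint("tragion_left", "tragion_right")

    @property
    def midectocanthi(self) -> np.ndarray:
        return self.midpoint("ectocanthus_left", "ectocanthus_right")

    def replace_points(self, points: Mapping[str, np.ndarray]) -> "LandmarkSet":
        return LandmarkSet(points=dict(points), frame_id=self.frame_id, time_s=self.time_s)


@dataclass
class FrameSequence:
    """Ordered, timestamped landmark frames at a nominal frame rate."""

    frames: list[LandmarkSet]
    nominal_fps: float = 10.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s is None and self.frames:
            self.duration_s = self.frames[-1].time_s + 1.0 / self.nominal_fps

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def validate(self) -> None:
        times = [f.time_s for f in self.frames]
        for t0, t1, f in zip(times, times[1:], self.frames[1:]):
            if t1 <= t0:
                raise SchemaError(
                    f"frame {f.frame_id}: time_s not strictly increasing "
                    f"({t1} after {t0})"
                )
        if self.frames:
            names0 = frozenset(self.frames[0].points)
            for f in self.frames[1:]:
                if frozenset(f.points) != names0:
                    raise SchemaError(
                        f"frame {f.frame_id}: landmark-name set differs from first frame"
                    )
        for f in self.frames:
            f.validate()


def template_head() -> LandmarkSet:
    """Canonical neutral-pose head, constructed so every deviation angle is zero.

    By construction: sellion-promentale is parallel to the vertical axis, the
    subnasale sits in the midsagittal plane, the ear-eye line (midtragion to
    midectocanthi) is elevated exactly 15 degrees above horizontal — the
    conventional neutral head orientation — and the acromion line is parallel
    to the lateral axis with its midpoint posterior-inferior to the head.
    Dimensions are plausible adult values in millimetres; the midtragion is at
    the origin.
    """
    e = 80.0  # midtragion -> midectocanthi distance, mm
    elev = math.radians(15.0)
    ey, ez = e * math.sin(elev), e * math.cos(elev)
    pts = {
        "tragion_right": (70.0, 0.0, 0.0),
        "tragion_left": (-70.0, 0.0, 0.0),
        "ectocanthus_right": (45.0, ey, ez),
        "ectocanthus_left": (-45.0, ey, ez),
        "sellion": (0.0, 25.0, 90.0),
        "promentale": (0.0, -45.0, 90.0),
        "subnasale": (0.0, -5.0, 95.0),
        "acromion_right": (180.0, -260.0, 10.0),
        "acromion_left": (-180.0, -260.0, 10.0),
        "infraorbitale_right": (35.0, 5.0, 80.0),
        "infraorbitale_left": (-35.0, 5.0, 80.0),
    }
    return LandmarkSet({k: np.array(v) for k, v in pts.items()}, frame_id=0, time_s=0.0)


# ---------------------------------------------------------------------------
# CSV / JSON round-trip I/O

_CSV_COLUMNS = ["frame_id", "time_s", "landmark", "x_mm", "y_mm", "z_mm"]


def _open_maybe(stream: str | Path | IO[str], mode: str):
    if isinstance(stream, (str, Path)):
        return open(stream, mode, encoding="utf-8"), True
    return stream, False


def read_frames(stream: str | Path | IO[str], format: str = "csv") -> FrameSequence:
    """Read a frame sequence from a long-form CSV or wide JSON stream.

    Landmark names are normalized to canonical tokens; unknown names are kept
    (and simply ignored by the geometry layer). Raises :class:`SchemaError` /
    :class:`ParseError` on missing required landmarks, non-numeric
    coordinates, duplicate (frame, landmark) rows or non-increasing
    timestamps.
    """
    fh, owns = _open_maybe(stream, "r")
    try:
        if format == "csv":
            seq = _read_csv(fh)
        elif format == "json":
            seq = _read_json(fh)
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if owns:
            fh.close()
    seq.validate()
    return seq


def _read_csv(fh: IO[str]) -> FrameSequence:
    try:
        df = pd.read_csv(fh, dtype={"landmark": str})
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"could not parse CSV: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"CSV is missing columns: {', '.join(missing)}")
    for col in ("frame_id", "time_s", "x_mm", "y_mm", "z_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"non-numeric value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"empty value in column {col!r} at line {line}")
        df[col] = coerced
    frames: list[LandmarkSet] = []
    for (fid, t), grp in df.groupby(["frame_id", "time_s"], sort=False):
        names = [canonical_landmark_name(n) for n in grp["landmark"]]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise SchemaError(f"frame {int(fid)}: duplicate landmark {dup!r}")
        pts = {
            n: np.array([r.x_mm, r.y_mm, r.z_mm])
            for n, (_, r) in zip(names, grp.iterrows())
        }
        frames.append(LandmarkSet(pts, frame_id=int(fid), time_s=float(t)))
    fids = [f.frame_id for f in frames]
    if len(set(fids)) != len(fids):
        raise SchemaError("a frame_id appears with two different time_s values")
    return FrameSequence(frames=frames)


def _read_json(fh: IO[str]) -> FrameSequence:
    try:
        records = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"could not parse JSON: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(records, list):
        raise SchemaError("JSON frame sequence must be a list of frame objects")
    frames = []
    for rec in records:
        try:
            pts = {k: np.asarray(v, dtype=float) for k, v in rec["points"].items()}
            frames.append(
                LandmarkSet(pts, frame_id=int(rec["frame_id"]), time_s=float(rec["time_s"]))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed JSON frame object: {exc}") from exc
    return FrameSequence(frames=frames)


def write_frames(seq: FrameSequence, stream: str | Path | IO[str], format: str = "csv") -> None:
    """Write a frame sequence; ``read_frames`` on the output is the identity
    (coordinates round-trip at full float precision)."""
    fh, owns = _open_maybe(stream, "w")
    try:
        if format == "csv":
            rows = [
                (f.frame_id, f.time_s, name, p[0], p[1], p[2])
                for f in seq.frames
                for name, p in f.points.items()
            ]
            pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(fh, index=False)
        elif format == "json":
            json.dump(
                [
                    {
                        "frame_id": f.frame_id,
                        "time_s": f.time_s,
                        "points": {k: list(v) for k, v in f.points.items()},
                    }
                    for f in seq.frames
                ],
                fh,
            )
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if owns:
            fh.close()


def write_angles_csv(
    per_frame: Iterable[tuple[int, float, "object"]],
    aggregate: "object",
    stream: str | Path | IO[str],
) -> None:
    """Write per-frame angle rows plus a final aggregate row flagged MODE.

    ``per_frame`` yields (frame_id, time_s, AngleSet); the aggregate AngleSet
    is written with ``frame_id=MODE`` and an empty time column.
    """
    fh, owns = _open_maybe(stream, "w")
    try:
        fh.write("frame_id,time_s,yaw_deg,roll_deg,pitch_deg,angle3d_deg\n")
        for fid, t, a in per_frame:
            fh.write(f"{fid},{t!r},{a.yaw_deg!r},{a.roll_deg!r},{a.pitch_deg!r},{a.angle3d_deg!r}\n")
        a = aggregate
        fh.write(f"MODE,,{a.yaw_deg!r},{a.roll_deg!r},{a.pitch_deg!r},{a.angle3d_deg!r}\n")
    finally:
        if owns:
            fh.close()
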