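"""Body alignment and head-deviation angles from anatomical landmarks.

The measurement model
---------------------
Each scan frame is first aligned to a body-fixed coordinate system using the
two acromia: the frame is rotated about the world vertical axis until the
horizontal projection of the acromion line points along +x (subject's right)
and translated so the acromion midpoint is the origin. Gravity is assumed to
coincide with the scanner's vertical axis, so only this transverse rotation is
determined by the shoulders.

Three head direction vectors are then read off the landmarks:

* ``roll_dir``  — unit vector from promentale to sellion (head "vertical"),
* ``yaw_dir``   — unit vector from the tragion midpoint to the subnasale,
* ``pitch_dir_raw`` — unit vector from the tragion midpoint to the
  ectocanthus midpoint (the ear-eye line).

The neutral head carries its ear-eye line 15° above horizontal, so a
neutral-corrected anterior vector ``pitch_dir_neutral`` is obtained by
rotating ``pitch_dir_raw`` down by the neutral offset about the head's
lateral axis. The composite deviation score is the angle between
``unit(roll_dir + pitch_dir_neutral)`` and the diagonal reference
``unit(0,1,1)``; it is zero for a neutral head and non-negative always.

Signed angles follow the clinical convention: rotation of the face toward
the subject's right → yaw > 0; head-top tilt toward the subject's right →
roll > 0; ear-eye line raised above the 15° neutral → pitch > 0.

Two scalar-angle modes exist. The default ``projected`` mode decouples the
axes: roll is measured first from the frontal-plane projection of
``roll_dir``, the remaining vectors are de-rolled about the anterior axis,
and yaw/pitch are taken from the transverse azimuth of ``yaw_dir`` and the
elevation of the ear-eye line. With this construction any single-axis
rotation of the neutral head is recovered exactly, with zero leakage into
the other two angles. The ``dot`` mode instead takes the plain arccos of
each direction vector with its reference, signed by the lateral component —
the literal dot-product reading, kept for fidelity comparisons; it conflates
axes (a pure pitch registers a spurious roll).

A 10 fps sequence is aggregated per angle by the modal value: values are
binned at 0.1°, and the mean of the most populated bin is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SchemaError
from .landmarks_io import FrameSequence, LandmarkSet

__all__ = [
    "GeometryConfig",
    "DirectionVectors",
    "AngleSet",
    "align_to_body",
    "direction_vectors",
    "head_angles",
    "frame_angles",
    "process_sequence",
    "modal_value",
]

_MIN_PAIR_SEP_MM = 1.0  # below sticker size, a direction is noise


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError("zero-length vector has no direction")
    return v / n


def _rot_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    th = math.radians(angle_deg)
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


@dataclass
class GeometryConfig:
    """Reference vectors and measurement options.

    ``vertical_ref``/``anterior_ref`` define the body frame (defaults (0,1,0)
    and (0,0,1)); ``diagonal_ref`` is their normalized sum and is the
    reference for the composite 3D angle. ``neutral_pitch_offset_deg`` is the
    elevation of the neutral ear-eye line above horizontal (15° by
    convention). ``mode_bin_deg`` is the bin width for modal aggregation.
    """

    vertical_ref: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    anterior_ref: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    diagonal_ref: np.ndarray | None = None
    neutral_pitch_offset_deg: float = 15.0
    angle_mode: str = "projected"
    mode_bin_deg: float = 0.1

    def __post_init__(self) -> None:
        self.vertical_ref = np.asarray(self.vertical_ref, dtype=float)
        self.anterior_ref = np.asarray(self.anterior_ref, dtype=float)
        for name in ("vertical_ref", "anterior_ref"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be unit-norm")
        if abs(float(self.vertical_ref @ self.anterior_ref)) > 1e-12:
            raise ValueError("vertical_ref and anterior_ref must be orthogonal")
        if self.diagonal_ref is None:
            self.diagonal_ref = _unit(self.vertical_ref + self.anterior_ref)
        else:
            self.diagonal_ref = np.asarray(self.diagonal_ref, dtype=float)
            if np.linalg.norm(self.diagonal_ref - _unit(self.vertical_ref + self.anterior_ref)) > 1e-9:
                raise ValueError("diagonal_ref must be unit(vertical_ref + anterior_ref)")
        if self.angle_mode not in ("projected", "dot"):
            raise ValueError(f"angle_mode must be 'projected' or 'dot', got {self.angle_mode!r}")
        if not self.mode_bin_deg > 0:
            raise ValueError("mode_bin_deg must be positive")

    @property
    def lateral_ref(self) -> np.ndarray:
        """+x of the body frame (subject's right), vertical × anterior."""
        return np.cross(self.vertical_ref, self.anterior_ref)


@dataclass
class DirectionVectors:
    """Unit head-direction vectors of one aligned frame."""

    roll_dir: np.ndarray
    yaw_dir: np.ndarray
    pitch_dir_raw: np.ndarray
    pitch_dir_neutral: np.ndarray
    dir3d: np.ndarray


@dataclass
class AngleSet:
    """Signed yaw/roll/pitch (degrees) and the non-negative composite angle."""

    yaw_deg: float
    roll_deg: float
    pitch_deg: float
    angle3d_deg: float

    def as_dict(self) -> dict[str, float]:
        return {
            "yaw_deg": self.yaw_deg,
            "roll_deg": self.roll_deg,
            "pitch_deg": self.pitch_deg,
            "angle3d_deg": self.angle3d_deg,
        }


def align_to_body(frame: LandmarkSet, cfg: GeometryConfig | None = None) -> LandmarkSet:
    """Rigidly align a frame to the body coordinate system.

    Rotates about the world vertical axis so the horizontal projection of
    acromion_right − acromion_left is parallel to +x, then translates the
    acromion midpoint to the origin. Inter-landmark distances are preserved.
    """
    cfg = cfg or GeometryConfig()
    frame.validate()
    a_r, a_l = frame["acromion_right"], frame["acromion_left"]
    line = a_r - a_l
    sep = float(np.linalg.norm(line))
    if sep <= _MIN_PAIR_SEP_MM:
        raise DegenerateGeometryError(
            f"frame {frame.frame_id}: acromions coincide ({sep:.3g} mm apart)"
        )
    u = line / sep
    # reject a shoulder line within 5° of vertical: its horizontal projection
    # no longer pins the transverse rotation
    if abs(float(u @ cfg.vertical_ref)) > math.cos(math.radians(5.0)):
        raise DegenerateGeometryError(
            f"frame {frame.frame_id}: acromion line within 5 degrees of vertical"
        )
    horiz = line - (line @ cfg.vertical_ref) * cfg.vertical_ref
    x_hat = cfg.lateral_ref
    # signed angle from horiz to x_hat about the vertical axis
    ang = math.atan2(
        float(np.cross(horiz, x_hat) @ cfg.vertical_ref), float(horiz @ x_hat)
    )
    R = _rot_about(cfg.vertical_ref, math.degrees(ang))
    mid = 0.5 * (a_r + a_l)
    new_pts = {name: R @ (p - mid) for name, p in frame.points.items()}
    return frame.replace_points(new_pts)


def direction_vectors(aligned: LandmarkSet, cfg: GeometryConfig | None = None) -> DirectionVectors:
    """Head direction vectors of an aligned frame (see module docstring).

    Orientation is normalized: ``roll_dir`` points up-ish (non-negative dot
    with the vertical reference), ``yaw_dir`` and ``pitch_dir_raw`` point
    forward-ish.
    """
    cfg = cfg or GeometryConfig()
    pairs = {
        "sellion-promentale": (aligned["sellion"], aligned["promentale"]),
        "subnasale-midtragion": (aligned["subnasale"], aligned.midtragion),
        "midectocanthi-midtragion": (aligned.midectocanthi, aligned.midtragion),
    }
    for label, (p, q) in pairs.items():
        if np.linalg.norm(p - q) <= _MIN_PAIR_SEP_MM:
            raise DegenerateGeometryError(
                f"frame {aligned.frame_id}: defining pair {label} closer than "
                f"{_MIN_PAIR_SEP_MM} mm"
            )

    def oriented(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
        u = _unit(v)
        return -u if float(u @ ref) < 0 else u

    roll_dir = oriented(aligned["sellion"] - aligned["promentale"], cfg.vertical_ref)
    yaw_dir = oriented(aligned["subnasale"] - aligned.midtragion, cfg.anterior_ref)
    pitch_dir_raw = oriented(aligned.midectocanthi - aligned.midtragion, cfg.anterior_ref)

    # neutral-corrected anterior head vector: lower the ear-eye line by the
    # neutral offset about the head's own lateral axis. The lateral axis is
    # taken as cross(roll_dir, pitch_dir_raw): it co-rotates rigidly with the
    # head, so the correction commutes with any head rotation and a purely
    # rolled head keeps its anterior vector unchanged.
    lat = np.cross(roll_dir, pitch_dir_raw)
    if np.linalg.norm(lat) < 1e-9:
        raise DegenerateGeometryError(
            f"frame {aligned.frame_id}: head vertical and ear-eye line parallel, "
            "lateral axis undefined"
        )
    R = _rot_about(_unit(lat), cfg.neutral_pitch_offset_deg)
    pitch_dir_neutral = R @ pitch_dir_raw

    s = roll_dir + pitch_dir_neutral
    if np.linalg.norm(s) < 1e-6:
        raise DegenerateGeometryError(
            f"frame {aligned.frame_id}: head vertical and anterior vectors antiparallel"
        )
    dir3d = _unit(s)
    return DirectionVectors(roll_dir, yaw_dir, pitch_dir_raw, pitch_dir_neutral, dir3d)


def head_angles(dirs: DirectionVectors, cfg: GeometryConfig | None = None) -> AngleSet:
    """Signed yaw/roll/pitch and composite 3D angle from direction vectors."""
    cfg = cfg or GeometryConfig()
    for name in ("roll_dir", "yaw_dir", "pitch_dir_raw", "pitch_dir_neutral", "dir3d"):
        if abs(np.linalg.norm(getattr(dirs, name)) - 1.0) > 1e-9:
            raise ValueError(f"{name} is not unit-norm")
    x_hat, y_hat, z_hat = cfg.lateral_ref, cfg.vertical_ref, cfg.anterior_ref

    roll = math.degrees(math.atan2(float(dirs.roll_dir @ x_hat), float(dirs.roll_dir @ y_hat)))

    if cfg.angle_mode == "projected":
        # de-roll yaw/pitch vectors about the anterior axis so a pure lateral
        # tilt leaks into neither of the other two angles
        R = _rot_about(z_hat, roll) if abs(roll) > 0 else np.eye(3)
        yv = R @ dirs.yaw_dir
        pv = R @ dirs.pitch_dir_raw
        yaw = math.degrees(math.atan2(float(yv @ x_hat), float(yv @ z_hat)))
        pitch = (
            math.degrees(math.asin(np.clip(float(pv @ y_hat), -1.0, 1.0)))
            - cfg.neutral_pitch_offset_deg
        )
    else:  # literal dot-product mode
        yaw = math.degrees(math.acos(np.clip(float(dirs.yaw_dir @ z_hat), -1.0, 1.0)))
        yaw *= float(np.sign(dirs.yaw_dir @ x_hat))
        roll = math.degrees(math.acos(np.clip(float(dirs.roll_dir @ y_hat), -1.0, 1.0)))
        roll *= float(np.sign(dirs.roll_dir @ x_hat))
        pitch = (
            math.degrees(math.asin(np.clip(float(dirs.pitch_dir_raw @ y_hat), -1.0, 1.0)))
            - cfg.neutral_pitch_offset_deg
        )

    # atan2(|u×v|, u·v) is the same angle as arccos(u·v) but keeps full
    # precision near 0°, where arccos loses half the significant digits
    angle3d = math.degrees(
        math.atan2(
            float(np.linalg.norm(np.cross(dirs.dir3d, cfg.diagonal_ref))),
            float(dirs.dir3d @ cfg.diagonal_ref),
        )
    )
    return AngleSet(yaw_deg=yaw, roll_deg=roll, pitch_deg=pitch, angle3d_deg=angle3d)


def frame_angles(frame: LandmarkSet, cfg: GeometryConfig | None = None) -> AngleSet:
    """Convenience: align one frame, form direction vectors, measure angles."""
    cfg = cfg or GeometryConfig()
    return head_angles(direction_vectors(align_to_body(frame, cfg), cfg), cfg)


def modal_value(values, bin_deg: float) -> float:
    """Most-frequent value of a continuous angle series.

    Values are assigned to half-open bins [k·bin_deg, (k+1)·bin_deg); the
    mean of the values in the most populated bin is returned. Ties go to the
    bin whose mean is closest to the overall median, then to the lower bin
    index.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("modal_value of an empty series")
    if not bin_deg > 0:
        raise ValueError("bin_deg must be positive")
    keys = np.floor(v / bin_deg).astype(np.int64)
    bins: dict[int, list[float]] = {}
    for k, x in zip(keys, v):
        bins.setdefault(int(k), []).append(float(x))
    top = max(len(m) for m in bins.values())
    med = float(np.median(v))
    candidates = sorted(
        (k for k, m in bins.items() if len(m) == top),
        key=lambda k: (abs(float(np.mean(bins[k])) - med), k),
    )
    return float(np.mean(bins[candidates[0]]))


def process_sequence(
    seq: FrameSequence, cfg: GeometryConfig | None = None
) -> tuple[list[AngleSet], AngleSet]:
    """Measure every frame independently and aggregate by modal value.

    Returns (per-frame AngleSets, aggregate AngleSet). The aggregate of each
    of yaw/roll/pitch/3D-angle is the modal value of its per-frame series at
    ``cfg.mode_bin_deg`` resolution.
    """
    cfg = cfg or GeometryConfig()
    if len(seq) == 0:
        raise SchemaError("cannot process an empty frame sequence")
    per_frame = [frame_angles(f, cfg) for f in seq]
    agg = AngleSet(
        yaw_deg=modal_value([a.yaw_deg for a in per_frame], cfg.mode_bin_deg),
        roll_deg=modal_value([a.roll_deg for a in per_frame], cfg.mode_bin_deg),
        pitch_deg=modal_value([a.pitch_deg for a in per_frame], cfg.mode_bin_deg),
        angle3d_deg=modal_value([a.angle3d_deg for a in per_frame], cfg.mode_bin_deg),
    )
    return per_frame, agg
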