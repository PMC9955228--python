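"""Flat key = value (TOML subset) serialization for configuration objects.

GeometryConfig, PoseSpec and CohortSpec round-trip through a flat TOML
dialect; nested cohort moments are flattened as ``<group>.<column>.mean``
style dotted keys. Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .head_geometry import GeometryConfig
from .synthetic import CohortSpec, PoseSpec

__all__ = ["load_config", "dump_config", "geometry_from_dict", "pose_from_dict", "cohort_from_dict"]


def load_config(path: str | Path) -> dict:
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise SchemaError(f"bad config file {path}: {exc}") from exc


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(float(x) if isinstance(x, (np.floating,)) else x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(values: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in values.items():
            fh.write(f"{k} = {_toml_scalar(v)}\n")


_GEOMETRY_KEYS = {
    "vertical_ref", "anterior_ref", "neutral_pitch_offset_deg", "angle_mode", "mode_bin_deg",
}
_POSE_KEYS = {"yaw_deg", "pitch_deg", "roll_deg", "translation", "landmark_noise_sd_mm", "seed"}
_COHORT_KEYS = {"n_per_group", "sign_flip_prob", "copula_rho", "family", "seed", "moments"}


def _checked(d: dict, allowed: set[str], what: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown {what} config keys: {', '.join(sorted(unknown))}")
    return d


def geometry_from_dict(d: dict) -> GeometryConfig:
    return GeometryConfig(**_checked(dict(d), _GEOMETRY_KEYS, "geometry"))


def pose_from_dict(d: dict) -> PoseSpec:
    return PoseSpec(**_checked(dict(d), _POSE_KEYS, "pose"))


def cohort_from_dict(d: dict) -> CohortSpec:
    d = _checked(dict(d), _COHORT_KEYS, "cohort")
    if "moments" in d:
        d["moments"] = {
            g: {c: tuple(v) for c, v in cols.items()} for g, cols in d["moments"].items()
        }
    return CohortSpec(**d)
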