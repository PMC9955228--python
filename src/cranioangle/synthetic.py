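"""Synthetic scan sequences and cohorts with known ground truth.

Two generators make every pipeline stage testable without scanner data:

* **Pose simulation** — rigid rotations of the neutral template head about
  the tragion midpoint, extrinsic order Ry(yaw)·Rx(pitch)·Rz(roll) under the
  package's sign conventions, plus translation and isotropic Gaussian
  landmark noise. The acromions receive translation and noise only, so body
  alignment and head pose stay independently controllable. Sequences emulate
  the capture protocol: 10 frames per second for 20 s, with per-frame
  Gaussian jitter on each angle.

* **Cohort simulation** — per-subject measurement magnitudes drawn to match
  published absolute-value means and SDs. The default family is the folded
  normal (the distribution of |X| for a signed normal deviation X), with the
  underlying (μ, σ) solved numerically from the target moments. Moment pairs
  with sd/mean above the half-normal ratio sqrt(π/2 − 1) ≈ 0.7555 are
  outside the folded-normal family; with ``family="auto"`` such columns fall
  back to a moment-matched gamma, otherwise they raise. Columns of one
  subject share a latent severity factor through a Gaussian copula, and
  signed columns share one random per-subject sign (the direction of the
  head deviation), so reliability and correlation analyses behave like real
  paired measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import StatsError
from .head_geometry import _rot_about
from .landmarks_io import FrameSequence, LandmarkSet, template_head

__all__ = [
    "PoseSpec",
    "CohortSpec",
    "TABLE1_MOMENTS",
    "apply_pose",
    "simulate_sequence",
    "fold_normal_params",
    "simulate_cohort",
    "table1_cohort_spec",
]

_HALF_NORMAL_RATIO = math.sqrt(math.pi / 2.0 - 1.0)

#: Published absolute-value moments (mean, SD in degrees) per group and
#: measurement for a 52/52 control/torticollis cohort; drives the default
#: cohort simulation.
TABLE1_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "goniometer_1": (1.13, 1.10),
        "goniometer_2": (1.15, 1.02),
        "still_photo": (1.38, 1.07),
        "yaw": (1.54, 0.91),
        "roll": (2.13, 1.60),
        "pitch": (5.78, 3.52),
        "angle3d": (3.60, 1.55),
    },
    "torticollis": {
        "goniometer_1": (6.67, 7.45),
        "goniometer_2": (6.77, 7.24),
        "still_photo": (6.98, 7.26),
        "yaw": (6.08, 5.97),
        "roll": (6.19, 6.33),
        "pitch": (10.37, 6.65),
        "angle3d": (11.07, 7.65),
    },
}

UNSIGNED_COLUMNS = ("angle3d",)


@dataclass
class PoseSpec:
    """Ground-truth head pose: rotation angles (deg), translation (mm), noise."""

    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    landmark_noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        for name in ("yaw_deg", "pitch_deg", "roll_deg"):
            if not abs(getattr(self, name)) < 90.0:
                raise ValueError(f"|{name}| must be < 90")
        if not (np.isfinite(self.landmark_noise_sd_mm) and self.landmark_noise_sd_mm >= 0):
            raise ValueError("landmark_noise_sd_mm must be finite and non-negative")


def _pose_matrix(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Extrinsic Ry(yaw)·Rx(pitch)·Rz(roll) under the package sign conventions:
    positive yaw turns the face right, positive pitch raises it, positive roll
    tilts the head-top right."""
    Ry = _rot_about(np.array([0.0, 1.0, 0.0]), yaw_deg)
    Rx = _rot_about(np.array([1.0, 0.0, 0.0]), -pitch_deg)  # RH about +x lowers +z
    Rz = _rot_about(np.array([0.0, 0.0, 1.0]), -roll_deg)   # RH about +z tilts left
    return Ry @ Rx @ Rz


_HEAD_EXCLUDED = ("acromion_left", "acromion_right")


def apply_pose(base: LandmarkSet, pose: PoseSpec) -> LandmarkSet:
    """Rotate the head landmarks about the midtragion, translate, add noise.

    Acromions are not rotated (the shoulders do not follow the head), so the
    body-alignment step sees an unchanged shoulder line.
    """
    base.validate()
    R = _pose_matrix(pose.yaw_deg, pose.pitch_deg, pose.roll_deg)
    pivot = base.midtragion
    rng = np.random.default_rng(pose.seed)
    pts = {}
    for name, p in base.points.items():
        q = p if name in _HEAD_EXCLUDED else pivot + R @ (p - pivot)
        pts[name] = q + pose.translation
    for name in pts:
        if pose.landmark_noise_sd_mm > 0:
            pts[name] = pts[name] + rng.normal(0.0, pose.landmark_noise_sd_mm, 3)
    return base.replace_points(pts)


def simulate_sequence(
    base: LandmarkSet | None = None,
    pose: PoseSpec | None = None,
    fps: float = 10.0,
    duration_s: float = 20.0,
    frame_jitter_deg: float = 0.3,
    seed: int = 0,
) -> FrameSequence:
    """Emulate a scan capture: floor(fps·duration) frames at timestamps k/fps.

    Each frame's pose is the nominal pose plus independent Gaussian jitter
    (SD ``frame_jitter_deg``) on each rotation angle; landmark noise follows
    the pose spec. All randomness derives from ``seed``.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration must be positive")
    base = base if base is not None else template_head()
    pose = pose or PoseSpec()
    n = int(math.floor(fps * duration_s))
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n):
        jit = rng.normal(0.0, frame_jitter_deg, 3) if frame_jitter_deg > 0 else np.zeros(3)
        fpose = PoseSpec(
            yaw_deg=pose.yaw_deg + jit[0],
            pitch_deg=pose.pitch_deg + jit[1],
            roll_deg=pose.roll_deg + jit[2],
            translation=pose.translation,
            landmark_noise_sd_mm=pose.landmark_noise_sd_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        f = apply_pose(base, fpose)
        f.frame_id, f.time_s = k, k / fps
        frames.append(f)
    return FrameSequence(frames=frames, nominal_fps=fps, duration_s=duration_s)


# ---------------------------------------------------------------------------
# cohort simulation

def fold_normal_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Underlying normal (μ, σ) whose folded distribution |N(μ,σ)| has the
    requested mean and SD, solved from the closed-form folded-normal moments.

    Raises :class:`StatsError` when sd/mean exceeds the half-normal ratio
    sqrt(π/2 − 1), the supremum attainable by any folded normal.
    """
    if target_mean <= 0 or target_sd < 0:
        raise StatsError("folded-normal targets need mean > 0 and sd >= 0")
    if target_sd == 0:
        return target_mean, 0.0
    ratio = target_sd / target_mean
    if ratio >= _HALF_NORMAL_RATIO:
        raise StatsError(
            f"sd/mean = {ratio:.4f} exceeds the folded-normal limit "
            f"{_HALF_NORMAL_RATIO:.4f}; no folded normal has these moments"
        )

    def m1(theta: float) -> float:  # E|N(theta, 1)|
        return math.sqrt(2 / math.pi) * math.exp(-theta**2 / 2) + theta * (
            1 - 2 * stats.norm.cdf(-theta)
        )

    def ratio_of(theta: float) -> float:
        m = m1(theta)
        return math.sqrt(max(theta**2 + 1 - m * m, 0.0)) / m

    # ratio_of decreases monotonically from the half-normal value at θ=0 to 0
    theta = optimize.brentq(lambda t: ratio_of(t) - ratio, 0.0, 60.0, xtol=1e-13)
    sigma = target_mean / m1(theta)
    return theta * sigma, sigma


def _magnitude_ppf(u: np.ndarray, mean: float, sd: float, family: str) -> np.ndarray:
    """Quantile function of the magnitude distribution matched to (mean, sd)."""
    if sd == 0:
        return np.full_like(u, mean)
    ratio = sd / mean
    use_gamma = family == "gamma" or (family == "auto" and ratio >= _HALF_NORMAL_RATIO)
    if use_gamma:
        shape = (mean / sd) ** 2
        return stats.gamma.ppf(u, shape, scale=sd**2 / mean)
    mu, sigma = fold_normal_params(mean, sd)
    return stats.foldnorm.ppf(u, c=mu / sigma, scale=sigma)


@dataclass
class CohortSpec:
    """Cohort generator parameters.

    ``moments`` maps group → measurement column → (absolute mean, SD) in
    degrees. ``copula_rho`` is the loading of each column on the per-subject
    latent severity factor (pairwise latent correlation ρ², Spearman ≈ 0.62
    at the default 0.8). ``sign_flip_prob`` is the probability that a
    subject's deviation points left; one sign is shared by all signed
    columns of that subject. ``family`` is "folded_normal" (strict, errors
    on infeasible moments), "gamma", or "auto" (folded normal where
    feasible, gamma otherwise).
    """

    moments: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(c) for g, c in TABLE1_MOMENTS.items()}
    )
    n_per_group: int = 52
    sign_flip_prob: float = 0.5
    copula_rho: float = 0.8
    family: str = "folded_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0 <= self.sign_flip_prob <= 1:
            raise ValueError("sign_flip_prob must be a probability")
        if not 0 <= self.copula_rho < 1:
            raise ValueError("copula_rho must lie in [0, 1)")
        if self.family not in ("folded_normal", "gamma", "auto"):
            raise ValueError(f"unknown magnitude family {self.family!r}")
        for g, cols in self.moments.items():
            for c, (m, s) in cols.items():
                if s < 0 or m <= 0:
                    raise ValueError(f"{g}/{c}: need mean > 0 and sd >= 0")


def table1_cohort_spec(seed: int = 0, n_per_group: int = 52) -> CohortSpec:
    """Cohort spec preset with the published group moments (family='auto':
    several comparator columns have sd/mean beyond the folded-normal range
    and use the gamma fallback)."""
    return CohortSpec(seed=seed, n_per_group=n_per_group, family="auto")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with the configured group moments and structure.

    Returns a DataFrame with ``subject_id``, ``group`` and one column per
    measurement; signed columns carry the per-subject sign, the 3D-angle
    column is always non-negative.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.copula_rho
    rows = []
    sid = 0
    for group, cols in spec.moments.items():
        names = list(cols)
        n = spec.n_per_group
        z = rng.normal(size=n)  # latent severity
        eps = rng.normal(size=(n, len(names)))
        u = stats.norm.cdf(rho * z[:, None] + math.sqrt(1 - rho**2) * eps)
        signs = np.where(rng.random(n) < spec.sign_flip_prob, -1.0, 1.0)
        mags = np.column_stack(
            [
                _magnitude_ppf(u[:, j], cols[c][0], cols[c][1], spec.family)
                for j, c in enumerate(names)
            ]
        )
        for i in range(n):
            row = {"subject_id": f"S{sid:04d}", "group": group}
            for j, c in enumerate(names):
                v = mags[i, j]
                row[c] = float(v if c in UNSIGNED_COLUMNS else signs[i] * v)
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
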