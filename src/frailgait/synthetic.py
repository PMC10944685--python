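"""Synthetic walking recordings and synthetic patient cohorts.

Two generators back the whole test strategy, because the clinical
recordings this package was designed for cannot be redistributed:

* :func:`simulate_walk` renders a parametrised walker on the L-shaped
  course (sit -> stand up -> 2 m lateral walk -> 90-degree right turn ->
  2 m frontal walk -> stop) as a 25-keypoint pixel time series at 30 fps,
  with optional Gaussian jitter and planted single-frame foot
  misdetections, returning full ground truth (phase boundaries, true
  gait parameters, spike frames) alongside the series.

* :func:`simulate_cohort` draws whole cohorts of 128-feature vectors,
  frailty labels (CFS 3-6) and survival outcomes whose gait-parameter
  distributions are anchored, per frailty level, to published
  derivation-cohort medians and inter-quartile ranges, with an
  exponential survival hazard increasing in the underlying continuous
  frailty level.

Walker geometry: the course lives in floor coordinates (u along the
first straight, w along the second); the turn is a quarter-circle arc of
small radius so the heading rotates smoothly.  Rendering uses a flat
scale of ``px_per_cm`` for the lateral straight and a mildly
depth-dependent scale for the frontal straight that integrates to the
exact marker-to-marker scale, so single-scalar per-segment calibration
remains exact in the large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .keypoints import BODY25, KeypointSeries
from .preprocess import CalibrationConfig
from .registry import NAMED_GAIT_FEATURES, STAT_FEATURES, feature_names

__all__ = [
    "WalkerParams",
    "WalkGroundTruth",
    "CohortParams",
    "simulate_walk",
    "preset_for_cfs",
    "simulate_cohort",
    "TABLE_GAIT_ANCHORS",
]

STRAIGHT_CM = 200.0  # chair->marker1 and marker1->marker2 distances


@dataclass(frozen=True)
class WalkerParams:
    """Kinematic and rendering parameters of the synthetic walker.

    ``cadence_steps_s`` defaults to ``gait_speed_cm_s / step_length_cm``
    so that speed, step length and cadence stay mutually consistent; if
    set explicitly it takes precedence and the stride length follows
    from speed and cadence.
    """

    gait_speed_cm_s: float = 93.1
    step_length_cm: float = 47.3
    cadence_steps_s: float | None = None
    stance_fraction: float = 0.548
    arm_swing_amp_cm: float = 20.0
    turn_duration_s: float = 2.63
    stand_up_duration_s: float = 1.0
    sit_duration_s: float = 2.5
    end_stand_duration_s: float = 2.0
    body_height_cm: float = 158.0
    body_mass_kg: float = 50.0
    fps: float = 30.0
    px_per_cm: float = 2.0
    jitter_px_sd: float = 0.0
    n_spikes: int = 0
    spike_magnitude_px: float = 80.0
    turn_radius_cm: float = 50.0
    depth_scale_amp: float = 0.03
    foot_lift_cm: float = 6.0
    bob_amp_cm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gait_speed_cm_s", "step_length_cm", "turn_duration_s",
            "stand_up_duration_s", "body_height_cm", "body_mass_kg",
            "fps", "px_per_cm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.5 < self.stance_fraction < 0.9:
            raise ValueError("stance_fraction must lie in (0.5, 0.9)")
        if self.turn_radius_cm >= STRAIGHT_CM:
            raise ValueError("turn radius must be shorter than the straights")

    @property
    def cadence(self) -> float:
        if self.cadence_steps_s is not None:
            return self.cadence_steps_s
        return self.gait_speed_cm_s / self.step_length_cm

    @property
    def stride_length_cm(self) -> float:
        return 2.0 * self.gait_speed_cm_s / self.cadence


@dataclass
class WalkGroundTruth:
    """Everything the generator knows that a consumer must recover."""

    stand_up: tuple[int, int]
    segment1: tuple[int, int]
    cornering: tuple[int, int]
    segment2: tuple[int, int]
    stop_frame: int
    gait_speed_cm_s: float
    stance_fraction: float
    cadence_steps_s: float
    step_length_cm: float
    total_gait_time_s: float
    cornering_time_s: float
    duration_s: float
    spike_frames: list[int]
    marker1_px: tuple[float, float]
    marker2_px: tuple[float, float]
    px_per_cm: float


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


_SWING_RAMP = 0.1  # fraction of swing spent accelerating / decelerating


def _swing_advance(tau: np.ndarray) -> np.ndarray:
    """Normalised foot advance over one swing, trapezoidal velocity.

    The foot accelerates over the first tenth of swing, cruises, and
    decelerates sharply over the last tenth -- the brisk terminal
    deceleration of a real swing phase, which also keeps the
    relative-excursion extremum close to foot contact.
    """
    r = _SWING_RAMP
    h = 1.0 / (1.0 - r)
    tau = np.clip(tau, 0.0, 1.0)
    return np.where(
        tau < r,
        h * tau**2 / (2.0 * r),
        np.where(
            tau <= 1.0 - r,
            h * (tau - r / 2.0),
            1.0 - h * (1.0 - tau) ** 2 / (2.0 * r),
        ),
    )


def _foot_residual(phi: np.ndarray, swing_frac: float) -> np.ndarray:
    """Zero-mean along-path oscillation of a foot, in stride-length units.

    Swing occupies the first ``swing_frac`` of the cycle, advancing one
    stride; the remainder is an exact stance plateau (zero velocity at
    constant body speed).
    """
    phi = np.mod(phi, 1.0)
    pos = np.where(
        phi < swing_frac, _swing_advance(phi / swing_frac), 1.0
    )
    return pos - phi - (1.0 - swing_frac) / 2.0


def _foot_lift(phi: np.ndarray, swing_frac: float, lift_cm: float) -> np.ndarray:
    phi = np.mod(phi, 1.0)
    return np.where(
        phi < swing_frac,
        lift_cm * np.sin(np.pi * phi / swing_frac),
        0.0,
    )


class _Course:
    """L-course path: arc-length -> (u, w, heading)."""

    def __init__(self, radius_cm: float):
        self.r = radius_cm
        self.l1 = STRAIGHT_CM - radius_cm
        self.arc = math.pi * radius_cm / 2.0
        self.l2 = STRAIGHT_CM - radius_cm
        self.total = self.l1 + self.arc + self.l2

    def point(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = np.clip(s, 0.0, self.total)
        u = np.empty_like(s)
        w = np.empty_like(s)
        heading = np.empty_like(s)
        m1 = s <= self.l1
        u[m1] = s[m1]
        w[m1] = 0.0
        heading[m1] = 0.0
        m2 = (s > self.l1) & (s <= self.l1 + self.arc)
        theta = (s[m2] - self.l1) / self.r
        u[m2] = self.l1 + self.r * np.sin(theta)
        w[m2] = self.r * (1.0 - np.cos(theta))
        heading[m2] = theta
        m3 = s > self.l1 + self.arc
        u[m3] = STRAIGHT_CM
        w[m3] = self.r + (s[m3] - self.l1 - self.arc)
        heading[m3] = math.pi / 2.0
        return u, w, heading


def simulate_walk(
    p: WalkerParams,
) -> tuple[KeypointSeries, WalkGroundTruth, CalibrationConfig]:
    """Render one walk; return the series, ground truth and calibration."""
    course = _Course(p.turn_radius_cm)
    if course.l1 < p.stride_length_cm:
        raise ValueError("course shorter than one stride")
    v = p.gait_speed_cm_s
    t_sit, t_su = p.sit_duration_s, p.stand_up_duration_s
    t1 = course.l1 / v
    t_turn = p.turn_duration_s
    t2 = course.l2 / v
    t_end = p.end_stand_duration_s
    bounds = np.cumsum([0.0, t_sit, t_su, t1, t_turn, t2, t_end])
    duration = float(bounds[-1])
    n = int(round(duration * p.fps))
    t = np.arange(n) / p.fps

    def frame_of(time_s: float) -> int:
        return min(int(round(time_s * p.fps)), n - 1)

    # --- along-path position of the pelvis -------------------------------
    s_b = np.zeros(n)
    in1 = (t >= bounds[2]) & (t < bounds[3])
    s_b[in1] = (t[in1] - bounds[2]) * v
    inturn = (t >= bounds[3]) & (t < bounds[4])
    arc_speed = course.arc / t_turn
    s_b[inturn] = course.l1 + (t[inturn] - bounds[3]) * arc_speed
    in2 = (t >= bounds[4]) & (t < bounds[5])
    s_b[in2] = course.l1 + course.arc + (t[in2] - bounds[4]) * v
    s_b[t >= bounds[5]] = course.total

    walking = (t >= bounds[2]) & (t < bounds[5])
    # smooth 0->1 gait gate, 0.3 s ramps at the walking-window edges
    ramp = 0.3
    gate = np.minimum(
        _smoothstep((t - bounds[2]) / ramp), _smoothstep((bounds[5] - t) / ramp)
    )
    gate[~((t >= bounds[2] - ramp) & (t < bounds[5] + ramp))] = 0.0

    # gait phase advances only while walking
    stride_rate = p.cadence / 2.0  # strides per second per foot
    phase = np.cumsum(walking) / p.fps * stride_rate

    sw = 1.0 - p.stance_fraction
    sl = p.stride_length_cm
    h = p.body_height_cm
    z_hip = 0.53 * h
    z_mid_sit = 50.0

    # vertical pelvis profile: seated -> stand-up smoothstep -> standing (+bob)
    z_mid = np.full(n, z_hip)
    z_mid[t < bounds[1]] = z_mid_sit
    su = (t >= bounds[1]) & (t < bounds[2])
    z_mid[su] = z_mid_sit + (z_hip - z_mid_sit) * _smoothstep(
        (t[su] - bounds[1]) / t_su
    )
    bob = p.bob_amp_cm * np.sin(2.0 * np.pi * p.cadence * t) * gate
    z_mid = z_mid + bob

    # --- per-keypoint (s, lateral, z, fore-aft) --------------------------
    # s offsets are along-path; lateral is +left of travel; z is height.
    torso_dz = z_mid - z_hip  # displaces the whole upper body during sit/stand
    arm = p.arm_swing_amp_cm * np.sin(2.0 * np.pi * phase) * gate

    foot_s: dict[str, np.ndarray] = {}
    foot_z: dict[str, np.ndarray] = {}
    for side, off in (("l", 0.0), ("r", 0.5)):
        phi = phase + off
        foot_s[side] = s_b + sl * _foot_residual(phi, sw) * gate
        foot_z[side] = _foot_lift(phi, sw, p.foot_lift_cm) * gate

    def leg_z(base: float) -> float:
        return base  # ground-referenced heights for foot chain

    spec: dict[str, tuple[np.ndarray | float, float, np.ndarray | float]] = {}
    # label -> (s_along, lateral, z)
    spec["midhip"] = (s_b, 0.0, z_mid)
    spec["neck"] = (s_b, 0.0, 0.85 * h + torso_dz)
    spec["nose"] = (s_b + 8.0, 0.0, 0.93 * h + torso_dz)
    spec["r_eye"] = (s_b + 7.0, -3.0, 0.95 * h + torso_dz)
    spec["l_eye"] = (s_b + 7.0, 3.0, 0.95 * h + torso_dz)
    spec["r_ear"] = (s_b, -7.0, 0.94 * h + torso_dz)
    spec["l_ear"] = (s_b, 7.0, 0.94 * h + torso_dz)
    for side, lat in (("r", -1.0), ("l", 1.0)):
        sh = 0.82 * h + torso_dz
        spec[f"{side}_shoulder"] = (s_b, lat * 11.0, sh)
        spec[f"{side}_elbow"] = (s_b + 0.5 * (arm if side == "r" else -arm),
                                 lat * 13.0, 0.63 * h + torso_dz)
        spec[f"{side}_wrist"] = (s_b + (arm if side == "r" else -arm),
                                 lat * 14.0, 0.47 * h + torso_dz)
        spec[f"{side}_hip"] = (s_b, lat * 9.0, z_mid)
        fs, fz = foot_s[side], foot_z[side]
        spec[f"{side}_ankle"] = (fs, lat * 9.0, 8.0 + fz)
        spec[f"{side}_heel"] = (fs - 7.0, lat * 9.0, 3.0 + fz)
        spec[f"{side}_bigtoe"] = (fs + 12.0, lat * 8.0, 2.0 + fz)
        spec[f"{side}_smalltoe"] = (fs + 10.0, lat * 12.0, 2.0 + fz)
        # knee: between hip and ankle with slight forward carry
        knee_s = 0.5 * (s_b + fs) + 4.0
        knee_z = 0.5 * (z_mid + 8.0 + fz)
        spec[f"{side}_knee"] = (knee_s, lat * 9.0, knee_z)

    # --- projection to pixels --------------------------------------------
    k = p.px_per_cm
    beta = p.depth_scale_amp
    x0, y0 = 100.0, 900.0

    def project(u: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
        y_ground = y0 + k * (w + beta * ((w - 100.0) ** 2 - 100.0**2) / 200.0)
        body_scale = k * (1.0 + beta * (w - 100.0) / 100.0)
        return np.stack([x0 + k * u, y_ground - z * body_scale], axis=-1)

    xy = np.empty((n, 25, 2))
    for label, (s_kp, lat, z_kp) in spec.items():
        s_arr = np.broadcast_to(np.asarray(s_kp, dtype=float), (n,))
        z_arr = np.broadcast_to(np.asarray(z_kp, dtype=float), (n,))
        u, w, heading = course.point(s_arr)
        # lateral offset perpendicular to travel (+left)
        u = u + lat * np.sin(heading)
        w = w - lat * np.cos(heading)
        xy[:, BODY25.index_of(label), :] = project(u, w, z_arr)

    rng = np.random.default_rng(p.seed)
    if p.jitter_px_sd > 0:
        xy = xy + rng.normal(0.0, p.jitter_px_sd, size=xy.shape)

    # --- planted single-frame foot misdetections -------------------------
    walk_frames = np.flatnonzero(walking)
    spike_frames: list[int] = []
    if p.n_spikes > 0:
        candidates = walk_frames[5:-5]
        chosen: list[int] = []
        order = rng.permutation(len(candidates))
        for i in order:
            f = int(candidates[i])
            if all(abs(f - c) >= 3 for c in chosen):
                chosen.append(f)
            if len(chosen) == p.n_spikes:
                break
        if len(chosen) < p.n_spikes:
            raise ValueError("walk too short to place the requested spikes")
        spike_frames = sorted(chosen)
        foot_labels = ("hip", "knee", "ankle", "bigtoe", "smalltoe", "heel")
        for f in spike_frames:
            # a misdetection locks onto a wrong location: the whole foot
            # is displaced by the spike magnitude *relative to its previous
            # frame*, so the observed frame-to-frame displacement equals
            # the configured magnitude exactly
            side = "l" if rng.random() < 0.5 else "r"
            for part in foot_labels:
                idx = BODY25.side(side, part)
                xy[f, idx, 0] = xy[f - 1, idx, 0] + p.spike_magnitude_px

    conf = np.full((n, 25), 0.9)
    series = KeypointSeries(xy, conf, fps=p.fps, subject_id=f"walker-{p.seed}")

    m1 = project(np.array([STRAIGHT_CM]), np.array([0.0]), np.array([0.0]))[0]
    m2 = project(np.array([STRAIGHT_CM]), np.array([STRAIGHT_CM]), np.array([0.0]))[0]
    truth = WalkGroundTruth(
        stand_up=(frame_of(bounds[1]), frame_of(bounds[2])),
        segment1=(frame_of(bounds[2]), frame_of(bounds[3])),
        cornering=(frame_of(bounds[3]), frame_of(bounds[4])),
        segment2=(frame_of(bounds[4]), frame_of(bounds[5])),
        stop_frame=frame_of(bounds[5]),
        gait_speed_cm_s=v,
        stance_fraction=p.stance_fraction,
        cadence_steps_s=p.cadence,
        step_length_cm=sl / 2.0,
        total_gait_time_s=float(bounds[5] - bounds[1]),
        cornering_time_s=t_turn,
        duration_s=duration,
        spike_frames=spike_frames,
        marker1_px=(float(m1[0]), float(m1[1])),
        marker2_px=(float(m2[0]), float(m2[1])),
        px_per_cm=k,
    )
    cal = CalibrationConfig(truth.marker1_px, truth.marker2_px, STRAIGHT_CM)
    return series, truth, cal


# ---------------------------------------------------------------------------
# presets anchored to the published derivation-cohort medians per CFS level
# ---------------------------------------------------------------------------

# per-level anchors: (gait speed cm/s, step length cm, stance fraction,
# cornering s, stand-up s, sit s, lead-out s, arm swing cm, mass kg, height cm)
_PRESETS = {
    3: (93.1, 47.3, 0.548, 2.63, 1.0, 2.5, 2.0, 20.0, 50.0, 158.0),
    4: (70.2, 35.2, 0.614, 3.73, 1.5, 2.0, 1.5, 14.0, 47.0, 156.0),
    5: (51.8, 26.5, 0.681, 5.13, 2.0, 1.5, 1.5, 9.0, 49.0, 154.0),
    6: (40.7, 20.0, 0.755, 7.93, 2.5, 0.75, 0.75, 6.0, 46.0, 152.0),
}


def preset_for_cfs(level: int, seed: int = 0, **overrides) -> WalkerParams:
    """Walker parameters whose gait medians match one frailty level."""
    if level not in _PRESETS:
        raise ValueError("CFS preset level must be one of 3, 4, 5, 6")
    speed, step, stance, turn, su, sit, end, arm, mass, height = _PRESETS[level]
    params = WalkerParams(
        gait_speed_cm_s=speed,
        step_length_cm=step,
        stance_fraction=stance,
        turn_duration_s=turn,
        stand_up_duration_s=su,
        sit_duration_s=sit,
        end_stand_duration_s=end,
        arm_swing_amp_cm=arm,
        body_mass_kg=mass,
        body_height_cm=height,
        seed=seed,
    )
    return replace(params, **overrides) if overrides else params


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

# Derivation-cohort per-CFS gait anchors: median and (q25, q75) per level
# 3, 4, 5, 6 for the nine named gait parameters.
TABLE_GAIT_ANCHORS: dict[str, tuple[tuple[float, ...], tuple[tuple[float, float], ...]]] = {
    "total_gait_time_s": ((5.52, 8.23, 11.2, 18.9),
                          ((4.98, 6.00), (7.08, 9.37), (9.67, 16.6), (15.3, 25.0))),
    "cornering_time_s": ((2.63, 3.73, 5.13, 7.93),
                         ((2.33, 2.97), (3.32, 4.22), (4.63, 6.70), (6.53, 10.4))),
    "gait_speed_cm_s": ((93.1, 70.2, 51.8, 40.7),
                        ((85.2, 101.0), (63.1, 73.8), (40.9, 56.0), (33.1, 45.3))),
    "gait_width_cm": ((47.3, 35.2, 26.5, 20.0),
                      ((43.0, 52.3), (31.1, 38.9), (21.6, 34.2), (19.5, 20.8))),
    "stance_phase_pct": ((54.8, 61.4, 68.1, 75.5),
                         ((51.7, 58.5), (58.7, 63.8), (58.7, 71.6), (64.0, 84.1))),
    "ankle_swing_speed_cm_s": ((211.0, 162.0, 123.0, 102.0),
                               ((195.0, 230.0), (150.0, 179.0), (104.0, 133.0),
                                (93.0, 111.0))),
    "wrist_swing_speed_cm_s": ((131.0, 94.0, 68.0, 52.0),
                               ((104.0, 158.0), (75.0, 116.0), (58.0, 78.0),
                                (46.0, 56.0))),
    "ankle_momentum_kgms": ((17.1, 12.3, 9.8, 7.5),
                            ((15.0, 20.7), (10.8, 14.5), (7.7, 13.0), (7.1, 8.2))),
    "wrist_momentum_kgms": ((5.53, 3.75, 2.89, 2.16),
                            ((4.39, 7.33), (3.08, 5.09), (2.28, 3.78), (1.81, 2.31))),
}

# continuous-frailty positions at which the per-level anchors sit
# (the per-level medians of the continuous frailty level)
_FL_ANCHORS = np.array([3.57, 4.35, 5.32, 6.07])

# frail-ward direction of each named parameter (+1 rises with frailty)
_PARAM_DIRECTION = {
    "total_gait_time_s": 1.0,
    "cornering_time_s": 1.0,
    "stance_phase_pct": 1.0,
    "gait_speed_cm_s": -1.0,
    "gait_width_cm": -1.0,
    "ankle_swing_speed_cm_s": -1.0,
    "wrist_swing_speed_cm_s": -1.0,
    "ankle_momentum_kgms": -1.0,
    "wrist_momentum_kgms": -1.0,
}

_IQR_TO_SD = 2.0 * 0.6744897501960817  # lognormal sigma = ln(q3/q1) / this


@dataclass(frozen=True)
class CohortParams:
    """Population structure of a simulated cohort.

    The default CFS prevalence is the derivation-cohort split
    108:64:18:4 over levels 3..6; gait-parameter distributions are the
    per-level log-normal fits of :data:`TABLE_GAIT_ANCHORS`.  Survival is
    exponential with log-hazard ``log_hr_per_fl`` per unit of continuous
    frailty above 3 and independent uniform censoring.
    """

    n_subjects: int = 194
    cfs_prevalence: tuple[float, float, float, float] = (108.0, 64.0, 18.0, 4.0)
    label_noise_sd: float = 0.1
    log_hr_per_fl: float = math.log(1.6)
    baseline_hazard_per_day: float = 1.6e-4
    censor_lo_days: float = 180.0
    censor_hi_days: float = 750.0
    latent_corr: float = 0.5
    stat_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be at least 8")
        if not all(p >= 0 for p in self.cfs_prevalence) or sum(self.cfs_prevalence) <= 0:
            raise ValueError("cfs_prevalence must be non-negative and sum > 0")

    @property
    def prevalence(self) -> np.ndarray:
        p = np.asarray(self.cfs_prevalence, dtype=float)
        return p / p.sum()


def _lognorm_params(name: str) -> tuple[np.ndarray, np.ndarray]:
    med, iqr = TABLE_GAIT_ANCHORS[name]
    mu = np.log(np.asarray(med))
    sigma = np.array([math.log(q3 / q1) / _IQR_TO_SD for q1, q3 in iqr])
    return mu, sigma


# fixed (registry-version-constant) loadings for the 114 statistic features
def _stat_loadings() -> list[tuple[str, str, float]]:
    """(feature, parent named parameter, base log-ratio) per stat feature."""
    rng = np.random.default_rng(20240612)
    out = []
    for f in STAT_FEATURES:
        kp = f.name.rsplit("_", 3)[0]
        if any(part in kp for part in ("ankle", "heel", "toe", "knee", "hip")):
            parent = "ankle_swing_speed_cm_s"
        elif any(part in kp for part in ("wrist", "elbow")):
            parent = "wrist_swing_speed_cm_s"
        else:
            parent = "gait_speed_cm_s"
        if f.name.endswith("vrange"):
            parent = "gait_width_cm"
        out.append((f.name, parent, float(rng.normal(0.0, 0.3))))
    return out


_STAT_LOADINGS = _stat_loadings()


def simulate_cohort(
    c: CohortParams,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw a cohort: (features 128-wide, actual CFS labels, subject records).

    The subject-record frame carries the continuous frailty level, the
    full set of clinical covariates used by the mortality risk score,
    NT-pro BNP, albumin, and the survival outcome (time_days, event).
    """
    rng = np.random.default_rng(c.seed)
    n = c.n_subjects
    levels = rng.choice(np.array([3, 4, 5, 6]), size=n, p=c.prevalence)
    offset = np.clip(rng.normal(0.45, 0.18, size=n), 0.03, 0.97)
    fl_true = levels + offset

    z_common = rng.normal(size=n)
    rho = c.latent_corr
    named = {}
    for name in TABLE_GAIT_ANCHORS:
        mu_a, sg_a = _lognorm_params(name)
        mu = np.interp(fl_true, _FL_ANCHORS, mu_a)
        sg = np.interp(fl_true, _FL_ANCHORS, sg_a)
        z = (rho * _PARAM_DIRECTION[name] * z_common
             + math.sqrt(1.0 - rho**2) * rng.normal(size=n))
        named[name] = np.exp(mu + sg * z)

    # clinical covariates (cohort-typical elderly HF population)
    age = np.clip(rng.normal(82.3, 4.9, size=n), 75.0, 100.0)
    male = rng.random(n) < 0.428
    height = np.where(male, rng.normal(162.0, 6.0, n), rng.normal(149.0, 6.0, n))
    bmi = np.exp(rng.normal(math.log(22.8), 0.14, size=n))
    weight = bmi * (height / 100.0) ** 2
    stick_p = 1.0 / (1.0 + np.exp(-(fl_true - 4.8) / 0.35))
    stick = rng.random(n) < stick_p

    cols: dict[str, np.ndarray] = {f.name: named[f.name] for f in NAMED_GAIT_FEATURES}
    for fname, parent, logratio in _STAT_LOADINGS:
        noise = rng.normal(0.0, c.stat_noise_sd, size=n)
        cols[fname] = named[parent] * math.exp(logratio) * np.exp(noise)
    cols["age_y"] = age
    cols["sex"] = male.astype(float)
    cols["height_cm"] = height
    cols["weight_kg"] = weight
    cols["walking_stick"] = stick.astype(float)
    features = pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject"))
    features = features[list(feature_names())]

    fl_rated = fl_true + rng.normal(0.0, c.label_noise_sd, size=n)
    actual = pd.Series(
        np.clip(np.floor(fl_rated).astype(int), 3, 6), name="actual_cfs",
        index=features.index,
    )

    # survival: exponential hazard in the true frailty level
    rate = c.baseline_hazard_per_day * np.exp(c.log_hr_per_fl * (fl_true - 3.0))
    death = rng.exponential(1.0 / rate)
    censor = rng.uniform(c.censor_lo_days, c.censor_hi_days, size=n)
    time_days = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    nyha = np.select([fl_true < 4.6, fl_true < 6.2], [2, 3], default=4)
    subjects = pd.DataFrame(
        {
            "fl_true": fl_true,
            "actual_cfs": actual,
            "age_y": age,
            "sex": male.astype(int),
            "height_cm": height,
            "weight_kg": weight,
            "walking_stick": stick.astype(int),
            "bmi_kgm2": bmi,
            "sbp_mmHg": np.clip(rng.normal(124.0, 20.0, size=n), 60.0, 250.0),
            "lvef_pct": np.clip(rng.normal(55.0, 13.0, size=n), 15.0, 75.0),
            "nyha_class": nyha,
            "current_smoker": (rng.random(n) < 0.351).astype(int),
            "diabetes": (rng.random(n) < 0.304).astype(int),
            "copd": (rng.random(n) < 0.067).astype(int),
            "hf_duration_gt18mo": (rng.random(n) < 0.5).astype(int),
            "creatinine_umolL": np.exp(rng.normal(math.log(85.0), 0.31, size=n)),
            "acei_arb_use": (rng.random(n) < 0.639).astype(int),
            "beta_blocker_use": (rng.random(n) < 0.629).astype(int),
            "ntprobnp_pgml": np.exp(rng.normal(math.log(770.0), 1.14, size=n)),
            "albumin_gdl": rng.normal(3.8, 0.4, size=n),
            "time_days": time_days,
            "event": event,
        },
        index=features.index,
    )
    return features, actual, subjects
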