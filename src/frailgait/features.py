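"""Walk-phase segmentation, gait-event detection and the 128-feature vector.

The L-shaped walk decomposes into stand-up, a first straight (lateral
camera view), a 90-degree right turn, a second straight (frontal view)
and a stop.  Phases are found from the pelvis (midhip) trajectory:
stand-up from sustained upward motion, the turn from the rotation rate
of the smoothed heading, the stop from the last frame of sustained
walking speed.

Gait events use relative-excursion extrema, the standard unbiased choice
for marker or pose data: a heel strike is the peak of the heel's forward
excursion relative to the pelvis (the heel's forward velocity minimum),
a toe-off is the peak of the pelvis's excursion relative to the big toe
(the onset of the toe's forward-velocity rise).

Feature extraction fills the fixed registry: nine named spatiotemporal
parameters, 114 per-keypoint trajectory statistics over the two
straights, and five clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .keypoints import KeypointSeries
from .preprocess import Calibration
from .registry import (
    CLINICAL_FEATURES,
    STAT_KEYPOINTS,
    feature_names,
)

__all__ = [
    "WalkPhases",
    "GaitEvents",
    "SegmentMassCoefficients",
    "SegmentationError",
    "InsufficientStridesError",
    "MissingClinicalError",
    "segment_phases",
    "detect_gait_events",
    "extract_features",
    "smooth_trajectories",
]

SMOOTH_WINDOW = 5  # frames; centred moving average applied before velocities


class SegmentationError(RuntimeError):
    """A walk phase could not be located; carries the phase name."""

    def __init__(self, phase: str, detail: str = ""):
        self.phase = phase
        super().__init__(f"could not locate phase {phase!r}" + (f": {detail}" if detail else ""))


class InsufficientStridesError(RuntimeError):
    pass


class MissingClinicalError(KeyError):
    pass


@dataclass(frozen=True)
class WalkPhases:
    """Half-open frame intervals of the walk, in temporal order."""

    stand_up: tuple[int, int]
    segment1: tuple[int, int]
    cornering: tuple[int, int]
    segment2: tuple[int, int]
    stop_frame: int

    def __post_init__(self) -> None:
        seq = [*self.stand_up, *self.segment1, *self.cornering, *self.segment2,
               self.stop_frame]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"phase intervals out of order: {seq}")

    @property
    def walking_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.segment1, self.segment2)


@dataclass
class GaitEvents:
    """Per-side ordered heel-strike and toe-off frame lists."""

    heel_strikes: dict[str, list[int]] = field(default_factory=lambda: {"l": [], "r": []})
    toe_offs: dict[str, list[int]] = field(default_factory=lambda: {"l": [], "r": []})

    def n_strikes(self) -> int:
        return sum(len(v) for v in self.heel_strikes.values())


@dataclass(frozen=True)
class SegmentMassCoefficients:
    """Fraction of body mass carried by the swinging limb.

    Defaults are whole-limb mass fractions from standard anthropometry:
    the full lower limb is ~16.1% of body mass and the full upper limb
    ~5.0%; with those, momentum = coeff x mass x swing speed lands on
    the magnitudes reported for elderly HF cohorts.
    """

    ankle_coeff: float = 0.161
    wrist_coeff: float = 0.050

    def __post_init__(self) -> None:
        if not (0 < self.ankle_coeff < 1 and 0 < self.wrist_coeff < 1):
            raise ValueError("mass coefficients must lie in (0, 1)")


def smooth_trajectories(xy: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average along the frame axis, edges replicated."""
    if window <= 1 or xy.shape[0] < 2:
        return xy.astype(float, copy=True)
    pad = window // 2
    padded = np.concatenate(
        [np.repeat(xy[:1], pad, axis=0), xy, np.repeat(xy[-1:], pad, axis=0)], axis=0
    )
    kernel = np.ones(window) / window
    return np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), 0, padded
    )


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def segment_phases(series: KeypointSeries, cal: Calibration) -> WalkPhases:
    """Locate stand-up, the two straights, the turn and the stop frame.

    Three smoothing scales are used on the pelvis trajectory: a short
    window for the stop (sharp speed drop), a medium one for the
    stand-up rise, and a stride-scale window for the travel heading so
    the step-frequency bob does not masquerade as heading rotation.
    """
    fps = series.fps
    scale = cal.cm_per_px()
    raw_mid = series.keypoint("midhip")
    mid_fast = smooth_trajectories(raw_mid, SMOOTH_WINDOW)
    mid_med = smooth_trajectories(raw_mid, max(SMOOTH_WINDOW, int(round(0.3 * fps)) | 1))
    vel_fast = np.gradient(mid_fast, axis=0) * fps
    vel_med = np.gradient(mid_med, axis=0) * fps
    speed_cm = np.linalg.norm(vel_fast, axis=1) * scale
    up_cm = -vel_med[:, 1] * scale  # image y grows downward

    # --- stand-up: first sustained upward pelvis motion ------------------
    min_run = max(2, int(round(0.2 * fps)))
    runs = [r for r in _runs_of(up_cm > 10.0) if r[1] - r[0] >= min_run]
    if not runs:
        raise SegmentationError("stand_up", "no sustained upward pelvis motion")
    rise_start, rise_end = runs[0]
    start = rise_start
    while start > 0 and up_cm[start - 1] > 2.0:
        start -= 1
    end = rise_end
    while end < len(up_cm) and up_cm[end] > 2.0:
        end += 1
    stand_up = (int(start), int(end))

    # --- stop: last frame of sustained walking speed ----------------------
    # half-height crossing of the final speed drop is an unbiased stop
    # estimate; the 75th percentile approximates straight-walk speed
    walk_speed = float(np.percentile(speed_cm[stand_up[1]:], 75))
    thr_stop = max(10.0, 0.5 * walk_speed)
    moving = np.flatnonzero(speed_cm > thr_stop)
    moving = moving[moving >= stand_up[1]]
    if moving.size == 0:
        raise SegmentationError("stop", "no walking motion after stand-up")
    stop_frame = int(moving[-1]) + 1

    # --- cornering: sustained rotation of the travel heading --------------
    # the step-frequency pelvis bob is removed with a zero-phase low-pass
    # before the velocity is normalised: in a slow turn the bob's vertical
    # velocity rivals the forward speed and would otherwise swamp the
    # heading.  Unit direction vectors (not velocities) are then smoothed,
    # so slow turn frames are not outvoted by fast straight frames.
    lo = stand_up[1] + int(round(0.5 * fps))
    slow_w = max(SMOOTH_WINDOW, int(round(1.0 * fps)) | 1)
    b_lp, a_lp = butter(4, min(0.8 / (fps / 2.0), 0.99))
    vel_lp = filtfilt(b_lp, a_lp, vel_fast, axis=0)
    sp = np.linalg.norm(vel_lp, axis=1)
    sp[sp == 0] = 1.0
    unit = vel_lp / sp[:, None]
    unit_s = smooth_trajectories(smooth_trajectories(unit, slow_w), slow_w)
    heading = np.unwrap(np.arctan2(unit_s[:, 1], unit_s[:, 0]))
    omega = np.abs(np.gradient(heading)) * fps  # rad/s
    thr = np.deg2rad(6.0)
    min_turn = max(2, int(round(0.3 * fps)))
    window = np.zeros_like(omega, dtype=bool)
    window[lo:stop_frame] = True
    turn_runs = [r for r in _runs_of((omega > thr) & window) if r[1] - r[0] >= min_turn]
    if not turn_runs:
        raise SegmentationError("cornering", "no sustained heading rotation")
    a, b = max(turn_runs, key=lambda r: r[1] - r[0])
    # refine to half-height crossings of the rotation-rate plateau; the
    # midpoint crossing of a smoothed step is an unbiased edge estimate
    core = omega[a + (b - a) // 4 : b - (b - a) // 4]
    plateau = float(np.median(core)) if core.size else float(np.median(omega[a:b]))
    half = plateau / 2.0
    while a < b and omega[a] <= half:
        a += 1
    while a > lo and omega[a - 1] > half:
        a -= 1
    while b > a and omega[b - 1] <= half:
        b -= 1
    while b < stop_frame and omega[b] > half:
        b += 1
    cornering = (int(a), int(b))

    if not stand_up[1] <= cornering[0] or not cornering[1] <= stop_frame:
        raise SegmentationError("cornering", "turn interval out of order")
    phases = WalkPhases(
        stand_up=stand_up,
        segment1=(stand_up[1], cornering[0]),
        cornering=cornering,
        segment2=(cornering[1], stop_frame),
        stop_frame=stop_frame,
    )
    if phases.segment1[1] - phases.segment1[0] < min_run:
        raise SegmentationError("segment1", "first straight is empty")
    if phases.segment2[1] - phases.segment2[0] < min_run:
        raise SegmentationError("segment2", "second straight is empty")
    return phases


def _travel_direction(series: KeypointSeries) -> np.ndarray:
    """Unit travel direction of the pelvis, smoothed at stride scale."""
    fps = series.fps
    slow = smooth_trajectories(
        series.keypoint("midhip"), max(SMOOTH_WINDOW, int(round(1.0 * fps)) | 1)
    )
    vel = np.gradient(slow, axis=0) * fps
    norm = np.linalg.norm(vel, axis=1)
    norm[norm == 0] = 1.0
    return vel / norm[:, None]


def detect_gait_events(series: KeypointSeries, phases: WalkPhases) -> GaitEvents:
    """Heel strikes and toe-offs per side from relative-excursion extrema.

    Excursions are the signed projection of (heel - pelvis), respectively
    (pelvis - big toe), onto the instantaneous travel direction, over the
    whole walking region from stand-up end to stop; strides legitimately
    span the turn, so events are not clipped at the straight-segment
    boundaries.
    """
    a, b = phases.stand_up[1], phases.stop_frame
    if b - a < 8:
        raise InsufficientStridesError("walking region too short")
    # light smoothing only: heavier windows smear the short frail swing
    # phase asymmetrically and bias the excursion extrema
    sm = smooth_trajectories(series.xy, 3)
    mid = sm[:, series.schema.index_of("midhip"), :]
    direction = _travel_direction(series)
    detrend_w = max(SMOOTH_WINDOW, int(round(1.0 * series.fps)) | 1)

    def _excursion(part: np.ndarray, ref: np.ndarray) -> np.ndarray:
        # stride-scale detrend removes the constant anatomical offset,
        # which would otherwise rotate into the travel direction during
        # the turn and swamp the stride oscillation
        d = part - ref
        osc = d - smooth_trajectories(d, detrend_w)
        return np.einsum("ij,ij->i", osc, direction)[a:b]

    events = GaitEvents()
    for side in ("l", "r"):
        heel = sm[:, series.schema.side(side, "heel"), :]
        toe = sm[:, series.schema.side(side, "bigtoe"), :]
        rel_heel = _excursion(heel, mid)
        rel_toe = _excursion(mid, toe)
        for signal, target in ((rel_heel, events.heel_strikes[side]),
                               (rel_toe, events.toe_offs[side])):
            prom = 0.3 * (np.percentile(signal, 95) - np.percentile(signal, 5))
            if prom <= 0:
                continue
            peaks, _ = find_peaks(signal, prominence=prom)
            target.extend(int(a + f) for f in peaks)
    for side in ("l", "r"):
        events.heel_strikes[side].sort()
        events.toe_offs[side].sort()
        if len(events.heel_strikes[side]) < 2:
            raise InsufficientStridesError(
                f"fewer than 2 heel strikes detected on side {side!r}"
            )
    return events


def _frame_scales(
    n: int, phases: WalkPhases, cal: Calibration
) -> np.ndarray:
    """Per-frame cm/px: segment scale inside the straights, base elsewhere."""
    scales = np.full(n, cal.cm_per_px())
    for which, (a, b) in zip((1, 2), phases.walking_intervals):
        scales[a:b] = cal.cm_per_px(which)
    return scales


def _stride_records(events: GaitEvents, side: str) -> list[tuple[int, int, int]]:
    """(strike, toe_off, next_strike) triplets of one side."""
    strikes = events.heel_strikes[side]
    offs = events.toe_offs[side]
    out = []
    for s1, s2 in zip(strikes, strikes[1:]):
        between = [o for o in offs if s1 < o < s2]
        if between:
            out.append((s1, between[0], s2))
    return out


def _swing_windows(events: GaitEvents, side: str) -> list[tuple[int, int]]:
    """Toe-off -> next-heel-strike windows of one side."""
    strikes = events.heel_strikes[side]
    out = []
    for o in events.toe_offs[side]:
        nxt = [s for s in strikes if s > o]
        if nxt:
            out.append((o, nxt[0]))
    return out


def extract_features(
    series: KeypointSeries,
    phases: WalkPhases,
    events: GaitEvents,
    clinical: Mapping[str, float],
    cal: Calibration,
    mass_coeffs: SegmentMassCoefficients | None = None,
) -> pd.Series:
    """Compute the full 128-entry feature vector for one recording.

    ``clinical`` must provide age_y, sex, height_cm, weight_kg and
    walking_stick; a missing entry raises :class:`MissingClinicalError`
    naming the field.
    """
    mass_coeffs = mass_coeffs or SegmentMassCoefficients()
    for f in CLINICAL_FEATURES:
        if f.name not in clinical:
            raise MissingClinicalError(f.name)

    fps = series.fps
    sm = smooth_trajectories(series.xy)
    vel = np.gradient(sm, axis=0) * fps  # px/s, per keypoint
    mid_idx = series.schema.index_of("midhip")
    mid = sm[:, mid_idx, :]

    out: dict[str, float] = {}
    out["total_gait_time_s"] = (phases.stop_frame - phases.stand_up[0]) / fps
    out["cornering_time_s"] = (phases.cornering[1] - phases.cornering[0]) / fps

    scales = _frame_scales(series.n_frames, phases, cal)

    # gait speed: calibrated midhip path length over the walking intervals
    path_cm = 0.0
    walk_frames = 0
    for which, (a, b) in zip((1, 2), phases.walking_intervals):
        scale = cal.cm_per_px(which)
        steps = np.linalg.norm(np.diff(mid[a:b], axis=0), axis=1)
        path_cm += float(steps.sum()) * scale
        walk_frames += b - a
    walking_time = walk_frames / fps
    out["gait_speed_cm_s"] = path_cm / walking_time if walking_time > 0 else np.nan

    # gait width: forward heel-to-heel separation at heel strike (step
    # length), projected on the travel direction, strikes in the straights
    direction = _travel_direction(series)
    heel_gap = (
        sm[:, series.schema.side("l", "heel"), :]
        - sm[:, series.schema.side("r", "heel"), :]
    )
    rel_gap = np.abs(np.einsum("ij,ij->i", heel_gap, direction))
    widths = []
    for side in ("l", "r"):
        for f in events.heel_strikes[side]:
            if any(a <= f < b for a, b in phases.walking_intervals):
                widths.append(rel_gap[f] * scales[f])
    out["gait_width_cm"] = float(np.median(widths)) if widths else np.nan

    # stance phase: mean stance/stride duration ratio
    ratios = [
        (o - s1) / (s2 - s1)
        for side in ("l", "r")
        for s1, o, s2 in _stride_records(events, side)
    ]
    out["stance_phase_pct"] = 100.0 * float(np.mean(ratios)) if ratios else np.nan

    # swing speeds: mean keypoint speed inside swing windows
    def _mean_speed(pairs: list[tuple[str, str]]) -> float:
        samples = []
        for label_side, window_side in pairs:
            idx = series.schema.index_of(label_side)
            sp = np.linalg.norm(vel[:, idx, :], axis=1) * scales
            for a, b in _swing_windows(events, window_side):
                if b > a:
                    samples.append(sp[a:b])
        if not samples:
            return float("nan")
        return float(np.concatenate(samples).mean())

    ankle_speed = _mean_speed([("l_ankle", "l"), ("r_ankle", "r")])
    # the arm swings with the contralateral leg
    wrist_speed = _mean_speed([("r_wrist", "l"), ("l_wrist", "r")])

    out["ankle_swing_speed_cm_s"] = ankle_speed
    out["wrist_swing_speed_cm_s"] = wrist_speed
    mass = float(clinical["weight_kg"])
    out["ankle_momentum_kgms"] = mass_coeffs.ankle_coeff * mass * ankle_speed / 100.0
    out["wrist_momentum_kgms"] = mass_coeffs.wrist_coeff * mass * wrist_speed / 100.0

    # 114 per-keypoint statistics over the two straights
    for kp in STAT_KEYPOINTS:
        idx = series.schema.index_of(kp)
        sp_px = np.linalg.norm(vel[:, idx, :], axis=1)
        for which, (a, b) in zip((1, 2), phases.walking_intervals):
            scale = cal.cm_per_px(which)
            seg = f"seg{which}"
            sp = sp_px[a:b] * scale
            ys = sm[a:b, idx, 1] * scale
            out[f"{kp}_{seg}_mean_speed"] = float(sp.mean()) if sp.size else np.nan
            out[f"{kp}_{seg}_max_speed"] = float(sp.max()) if sp.size else np.nan
            out[f"{kp}_{seg}_vrange"] = (
                float(ys.max() - ys.min()) if ys.size else np.nan
            )

    for f in CLINICAL_FEATURES:
        out[f.name] = float(clinical[f.name])

    vector = pd.Series(out, name=series.subject_id)
    return vector[list(feature_names())]
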