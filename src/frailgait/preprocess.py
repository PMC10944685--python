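"""Camera calibration and foot-misdetection correction.

Calibration converts pixel displacements to centimetres from the two
floor markers placed 2 m apart on the walking course: the base scale is
``marker_distance_cm / ||marker1 - marker2||``, optionally refined with a
separate marker pair per walk segment.  No homography is attempted; each
straight segment gets one scalar scale.

Frame-to-frame pose estimation is independent per frame, so the left and
right foot are occasionally swapped or misplaced for a single frame.
Such frames are found by an asymmetric displacement test -- a monitored
keypoint moving more than +50 px in the positive direction or more than
35 px in the negative direction along either image axis relative to its
last valid location marks the frame abnormal -- after which all 12
lower-limb keypoints in the abnormal frame are deleted and re-filled by
cubic-spline interpolation through neighbouring valid frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.interpolate import CubicSpline

from .keypoints import BODY25, KeypointSeries

__all__ = [
    "CalibrationConfig",
    "Calibration",
    "AnomalyConfig",
    "CorrectionReport",
    "DegenerateCalibrationError",
    "calibrate",
    "detect_abnormal_frames",
    "correct_series",
]


class DegenerateCalibrationError(ValueError):
    """Markers coincide (or a segment pair does): no pixel scale exists."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Floor-marker pixel locations and their real separation.

    ``segment_marker_pairs`` optionally maps a walk-segment number (1 or
    2) to its own ((x, y), (x, y)) pixel pair when a segment-specific
    scale is wanted; otherwise both segments share the base scale.
    """

    marker1_px: tuple[float, float]
    marker2_px: tuple[float, float]
    marker_distance_cm: float = 200.0
    segment_marker_pairs: dict[int, tuple[tuple[float, float], tuple[float, float]]] = (
        field(default_factory=dict)
    )

    def __post_init__(self) -> None:
        if not self.marker_distance_cm > 0:
            raise ValueError("marker_distance_cm must be positive")


@dataclass(frozen=True)
class Calibration:
    """Resolved cm-per-pixel scales, one per straight walk segment."""

    base_cm_per_px: float
    segment_scales: dict[int, float]

    def cm_per_px(self, segment: int | None = None) -> float:
        if segment is None:
            return self.base_cm_per_px
        return self.segment_scales.get(segment, self.base_cm_per_px)


def _pair_scale(p1, p2, distance_cm: float) -> float:
    d = float(np.hypot(p1[0] - p2[0], p1[1] - p2[1]))
    if d == 0.0:
        raise DegenerateCalibrationError("marker pixel locations coincide")
    return distance_cm / d


def calibrate(series: KeypointSeries, cal: CalibrationConfig) -> Calibration:
    """Derive cm/px scales from the floor markers.

    The series argument is accepted for interface symmetry (scales are a
    property of the camera setup, not of the subject's motion).
    """
    base = _pair_scale(cal.marker1_px, cal.marker2_px, cal.marker_distance_cm)
    seg = {
        k: _pair_scale(p1, p2, cal.marker_distance_cm)
        for k, (p1, p2) in cal.segment_marker_pairs.items()
    }
    return Calibration(base_cm_per_px=base, segment_scales=seg)


@dataclass(frozen=True)
class AnomalyConfig:
    """Asymmetric per-axis displacement thresholds, in pixels."""

    pos_threshold_px: float = 50.0
    neg_threshold_px: float = 35.0
    monitored_keypoints: frozenset[int] = field(
        default_factory=lambda: BODY25.lower_limb_set
    )

    def __post_init__(self) -> None:
        if not (self.pos_threshold_px > 0 and self.neg_threshold_px > 0):
            raise ValueError("thresholds must be positive")


@dataclass
class CorrectionReport:
    """Which frames were abnormal and why.

    ``triggers`` records (frame, keypoint_index, axis, signed
    displacement) for every threshold violation; ``boundary_extended``
    lists frames filled by nearest-valid extension because an abnormal
    run touched the series boundary.
    """

    abnormal_frames: list[int] = field(default_factory=list)
    triggers: list[tuple[int, int, int, float]] = field(default_factory=list)
    keypoints_interpolated: int = 0
    boundary_extended: list[int] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {"frame": f, "keypoint": k, "axis": "xy"[a], "displacement_px": d}
            for f, k, a, d in self.triggers
        ]


def detect_abnormal_frames(
    series: KeypointSeries, cfg: AnomalyConfig | None = None
) -> CorrectionReport:
    """Flag frames whose monitored keypoints jump beyond the thresholds.

    Each frame is compared against the *last valid location* of each
    monitored keypoint -- i.e. its position in the most recent frame that
    was neither abnormal nor missing.  Comparing against the raw previous
    frame would flag the return jump after every single-frame spike as a
    second (spurious) anomaly.
    """
    cfg = cfg or AnomalyConfig()
    report = CorrectionReport()
    n = series.n_frames
    if n < 2:
        return report
    monitored = sorted(cfg.monitored_keypoints)
    last_xy = {k: None for k in monitored}  # type: dict[int, np.ndarray | None]
    for k in monitored:
        if series.conf[0, k] > 0:
            last_xy[k] = series.xy[0, k]
    for t in range(1, n):
        frame_triggers = []
        for k in monitored:
            if series.conf[t, k] <= 0 or last_xy[k] is None:
                continue
            delta = series.xy[t, k] - last_xy[k]
            for axis in (0, 1):
                d = float(delta[axis])
                if d > cfg.pos_threshold_px or d < -cfg.neg_threshold_px:
                    frame_triggers.append((t, k, axis, d))
        if frame_triggers:
            report.abnormal_frames.append(t)
            report.triggers.extend(frame_triggers)
        else:
            for k in monitored:
                if series.conf[t, k] > 0:
                    last_xy[k] = series.xy[t, k]
    return report


def _fill_runs(values: np.ndarray, valid: np.ndarray,
               report: CorrectionReport) -> np.ndarray:
    """Cubic-spline refill of invalid runs of a 1-D signal.

    Each invalid run is interpolated from up to 4 valid frames on each
    side.  Runs touching the series boundary are extended with the
    nearest valid value (no spline extrapolation).
    """
    out = values.copy()
    n = len(values)
    idx = np.flatnonzero(~valid)
    if idx.size == 0:
        return out
    if not valid.any():
        return out  # nothing to anchor on; leave untouched
    runs: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    valid_idx = np.flatnonzero(valid)
    for a, b in runs:
        left = valid_idx[valid_idx < a][-4:]
        right = valid_idx[valid_idx > b][:4]
        support = np.concatenate([left, right])
        if left.size == 0 or right.size == 0:
            # boundary run: nearest-valid extension
            anchor = right[0] if left.size == 0 else left[-1]
            out[a : b + 1] = values[anchor]
            for t in range(a, b + 1):
                if t not in report.boundary_extended:
                    report.boundary_extended.append(t)
            continue
        if support.size >= 4:
            spline = CubicSpline(support, values[support])
        else:
            # too few anchors for a cubic: fall back to linear bridge
            spline = CubicSpline(
                np.array([left[-1], right[0]]),
                values[[left[-1], right[0]]],
                bc_type="natural",
            )
        out[a : b + 1] = spline(np.arange(a, b + 1))
    return out


def correct_series(
    series: KeypointSeries, report: CorrectionReport,
    cfg: AnomalyConfig | None = None,
) -> KeypointSeries:
    """Delete lower-limb keypoints in abnormal frames and re-fill by spline.

    In every abnormal frame all monitored keypoints are treated as
    deleted (the misdetection typically swaps the whole foot), and
    missing detections (confidence 0) of monitored keypoints are filled
    the same way.  Frames and keypoints outside the abnormal set are
    returned bit-identical.
    """
    cfg = cfg or AnomalyConfig()
    out = series.copy()
    n = series.n_frames
    if n == 0:
        return out
    abnormal = np.zeros(n, dtype=bool)
    abnormal[np.asarray(report.abnormal_frames, dtype=int)] = True
    for k in sorted(cfg.monitored_keypoints):
        valid = (~abnormal) & (series.conf[:, k] > 0)
        if valid.all():
            continue
        refill = ~valid
        for axis in (0, 1):
            out.xy[:, k, axis] = _fill_runs(series.xy[:, k, axis], valid, report)
        # confidence of re-filled points: mean of the valid frames' confidence
        if valid.any():
            out.conf[refill, k] = float(series.conf[valid, k].mean())
        report.keypoints_interpolated += int(refill.sum())
    # de-duplicate boundary bookkeeping
    report.boundary_extended = sorted(set(report.boundary_extended))
    return out
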