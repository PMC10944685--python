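"""Phase segmentation, gait events and feature extraction against ground truth."""

import numpy as np
import pandas as pd
import pytest

from frailgait.features import (
    InsufficientStridesError,
    SegmentationError,
    WalkPhases,
    detect_gait_events,
    extract_features,
    segment_phases,
    smooth_trajectories,
)
from frailgait.keypoints import BODY25, KeypointSeries
from frailgait.preprocess import Calibration, CalibrationConfig, calibrate
from frailgait.registry import N_FEATURES, N_VIDEO_FEATURES, video_feature_names
from frailgait.synthetic import preset_for_cfs, simulate_walk
from tests.conftest import CLINICAL


@pytest.mark.parametrize("level", [3, 4, 5, 6])
def test_phase_boundaries_within_5_frames_of_ground_truth(level, walk_cache):
    series, truth, _, cal, _ = walk_cache(level)
    phases = segment_phases(series, cal)
    assert abs(phases.stand_up[0] - truth.stand_up[0]) <= 5
    assert abs(phases.stand_up[1] - truth.stand_up[1]) <= 5
    assert abs(phases.cornering[0] - truth.cornering[0]) <= 5
    assert abs(phases.cornering[1] - truth.cornering[1]) <= 5
    assert abs(phases.stop_frame - truth.stop_frame) <= 5


def test_static_series_raises_stand_up_error():
    xy = np.full((200, 25, 2), 300.0)
    series = KeypointSeries(xy, np.full((200, 25), 0.9))
    cal = Calibration(0.5, {})
    with pytest.raises(SegmentationError, match="stand_up"):
        segment_phases(series, cal)


def test_walk_without_turn_raises_cornering_error(walk_cache):
    series, truth, _, cal, _ = walk_cache(3)
    cut = truth.cornering[0] - 5  # keep stand-up and most of segment 1 only
    trimmed = KeypointSeries(series.xy[:cut].copy(), series.conf[:cut].copy(),
                             fps=series.fps)
    with pytest.raises(SegmentationError, match="cornering"):
        segment_phases(trimmed, cal)


def test_phase_intervals_are_ordered_and_contiguous(cfs4_walk):
    series, _, _, cal, _ = cfs4_walk
    phases = segment_phases(series, cal)
    assert phases.stand_up[1] == phases.segment1[0]
    assert phases.segment1[1] == phases.cornering[0]
    assert phases.cornering[1] == phases.segment2[0]
    assert phases.segment2[1] == phases.stop_frame


def test_out_of_order_phases_rejected():
    with pytest.raises(ValueError):
        WalkPhases((10, 5), (5, 20), (20, 30), (30, 40), 40)


class TestGaitEvents:
    def test_strike_count_matches_cadence(self, walk_cache):
        # 1.8 steps/s over 5 s of straight walking -> 9 +/- 1 strikes
        series, truth, _, cal, _ = walk_cache(
            4, gait_speed_cm_s=60.0, step_length_cm=60.0 / 1.8,
            stance_fraction=0.60,
        )
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        walking_s = (
            phases.segment1[1] - phases.segment1[0]
            + phases.segment2[1] - phases.segment2[0]
        ) / series.fps
        expected = 1.8 * (walking_s + truth.cornering_time_s)
        assert events.n_strikes() == pytest.approx(expected, abs=2)

    @pytest.mark.parametrize("level", [3, 5])
    def test_events_alternate_within_each_side(self, level, walk_cache):
        series, _, _, cal, _ = walk_cache(level)
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        for side in ("l", "r"):
            merged = sorted(
                [(f, "strike") for f in events.heel_strikes[side]]
                + [(f, "off") for f in events.toe_offs[side]]
            )
            kinds = [k for _, k in merged]
            assert all(a != b for a, b in zip(kinds, kinds[1:])), side

    def test_stance_fraction_recovered_within_3_points(self, walk_cache):
        series, truth, _, cal, _ = walk_cache(4)
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        vec = extract_features(series, phases, events, CLINICAL, cal)
        assert vec["stance_phase_pct"] == pytest.approx(
            100 * truth.stance_fraction, abs=3.0
        )

    def test_too_short_walk_raises_insufficient_strides(self, walk_cache):
        series, truth, _, cal, _ = walk_cache(3)
        phases = segment_phases(series, cal)
        stub = WalkPhases(
            phases.stand_up,
            (phases.stand_up[1], phases.stand_up[1] + 3),
            (phases.stand_up[1] + 3, phases.stand_up[1] + 4),
            (phases.stand_up[1] + 4, phases.stand_up[1] + 6),
            phases.stand_up[1] + 6,
        )
        with pytest.raises(InsufficientStridesError):
            detect_gait_events(series, stub)


def _constant_speed_fixture(speed_cm_s=80.0, px_per_cm=2.0, n=300, fps=30.0):
    """Straight constant-speed walk with fabricated stepping oscillation."""
    t = np.arange(n) / fps
    xy = np.zeros((n, 25, 2))
    xy[:, :, 1] = 500.0
    base = 100.0 + speed_cm_s * px_per_cm * t
    xy[:, :, 0] = base[:, None]
    for side, phase in (("l", 0.0), ("r", np.pi)):
        osc = 40.0 * np.sin(2 * np.pi * 0.9 * t + phase)
        xy[:, BODY25.side(side, "heel"), 0] += osc
        xy[:, BODY25.side(side, "bigtoe"), 0] += osc
        xy[:, BODY25.side(side, "ankle"), 0] += osc
    series = KeypointSeries(xy, np.full((n, 25), 0.9), fps=fps)
    cal = calibrate(series, CalibrationConfig((0.0, 0.0), (200.0 * px_per_cm, 0.0)))
    phases = WalkPhases((0, 2), (2, n // 2), (n // 2, n // 2 + 2),
                        (n // 2 + 2, n - 2), n - 2)
    return series, cal, phases


class TestExtraction:
    def test_feature_vector_has_fixed_registry_shape(self, cfs4_walk):
        series, _, _, cal, _ = cfs4_walk
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        vec = extract_features(series, phases, events, CLINICAL, cal)
        assert len(vec) == N_FEATURES == 128
        video = vec[list(video_feature_names())]
        assert len(video) == N_VIDEO_FEATURES == 123
        assert not vec.isna().any()

    def test_missing_clinical_field_error_names_it(self, cfs4_walk):
        series, _, _, cal, _ = cfs4_walk
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        clinical = {k: v for k, v in CLINICAL.items() if k != "weight_kg"}
        with pytest.raises(KeyError, match="weight_kg"):
            extract_features(series, phases, events, clinical, cal)

    def test_constant_speed_fixture_recovers_80_cm_s_within_1pct(self):
        series, cal, phases = _constant_speed_fixture(80.0)
        events = detect_gait_events(series, phases)
        vec = extract_features(series, phases, events, CLINICAL, cal)
        assert vec["gait_speed_cm_s"] == pytest.approx(80.0, rel=0.01)

    def test_scale_equivariance_of_cm_denominated_features(self, walk_cache):
        vecs = {}
        for ppc in (2.0, 4.0):
            series, _, _, cal, p = walk_cache(4, px_per_cm=ppc)
            phases = segment_phases(series, cal)
            events = detect_gait_events(series, phases)
            vecs[ppc] = extract_features(series, phases, events, CLINICAL, cal)
        for name in ("gait_speed_cm_s", "gait_width_cm", "stance_phase_pct",
                     "ankle_swing_speed_cm_s", "total_gait_time_s"):
            assert vecs[2.0][name] == pytest.approx(vecs[4.0][name], rel=0.01), name

    def test_momentum_is_mass_fraction_times_swing_speed(self, cfs4_walk):
        series, _, _, cal, p = cfs4_walk
        phases = segment_phases(series, cal)
        events = detect_gait_events(series, phases)
        vec = extract_features(series, phases, events, CLINICAL, cal)
        expected = 0.161 * CLINICAL["weight_kg"] * vec["ankle_swing_speed_cm_s"] / 100
        assert vec["ankle_momentum_kgms"] == pytest.approx(expected)

    def test_frailty_ordering_monotone_across_presets(self, walk_cache):
        rows = {}
        for level in (3, 4, 5, 6):
            series, _, _, cal, _ = walk_cache(level)
            phases = segment_phases(series, cal)
            events = detect_gait_events(series, phases)
            rows[level] = extract_features(series, phases, events, CLINICAL, cal)
        df = pd.DataFrame(rows).T
        assert df["gait_speed_cm_s"].is_monotonic_decreasing
        assert df["total_gait_time_s"].is_monotonic_increasing
        assert df["stance_phase_pct"].is_monotonic_increasing


def test_time_reversal_preserves_speed_magnitudes(rng):
    xy = rng.normal(size=(120, 25, 2)).cumsum(axis=0)
    sm = smooth_trajectories(xy)
    sp = np.linalg.norm(np.gradient(sm, axis=0), axis=2)
    sm_r = smooth_trajectories(xy[::-1])
    sp_r = np.linalg.norm(np.gradient(sm_r, axis=0), axis=2)
    assert np.allclose(sp[2:-2], sp_r[::-1][2:-2])
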