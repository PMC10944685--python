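"""The versioned 128-feature registry.

The model consumes a fixed, ordered vector of 128 features per subject:
9 named spatiotemporal gait parameters, 114 per-keypoint trajectory
statistics, and 5 clinical covariates (123 video-derived + 5 clinical).

The 114 statistics are deterministic by construction: for each of 19
body keypoints (the 25-keypoint schema minus the five head landmarks,
which duplicate the neck for gait purposes, and minus the midhip, whose
kinematics the named parameters already summarise), on each of the two
straight walk segments, three statistics of the calibrated smoothed
trajectory are taken: mean speed, maximum speed, and vertical excursion
range.  19 x 2 x 3 = 114.

Any change to names, order or definitions must bump REGISTRY_VERSION;
the trained-model artifact records the version it was fitted against.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .keypoints import BODY25

__all__ = [
    "REGISTRY_VERSION",
    "FeatureDef",
    "NAMED_GAIT_FEATURES",
    "CLINICAL_FEATURES",
    "STAT_KEYPOINTS",
    "STAT_SEGMENTS",
    "STAT_KINDS",
    "feature_registry",
    "feature_names",
    "video_feature_names",
    "N_FEATURES",
    "N_VIDEO_FEATURES",
]

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class FeatureDef:
    name: str
    unit: str
    kind: str  # "named" | "stat" | "clinical"
    definition: str


NAMED_GAIT_FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("total_gait_time_s", "s", "named",
               "time from stand-up onset to the stop frame"),
    FeatureDef("cornering_time_s", "s", "named",
               "duration of the 90-degree right turn between the straights"),
    FeatureDef("gait_speed_cm_s", "cm/s", "named",
               "calibrated midhip path length over the walking intervals "
               "divided by walking time"),
    FeatureDef("gait_width_cm", "cm", "named",
               "median forward heel-to-heel distance at heel strike "
               "(step length)"),
    FeatureDef("stance_phase_pct", "%", "named",
               "mean stance/stride duration ratio x 100"),
    FeatureDef("ankle_swing_speed_cm_s", "cm/s", "named",
               "mean calibrated ankle speed during that side's swing"),
    FeatureDef("wrist_swing_speed_cm_s", "cm/s", "named",
               "mean calibrated wrist speed during the contralateral swing"),
    FeatureDef("ankle_momentum_kgms", "kg*m/s", "named",
               "lower-limb mass fraction x body mass x ankle swing speed"),
    FeatureDef("wrist_momentum_kgms", "kg*m/s", "named",
               "upper-limb mass fraction x body mass x wrist swing speed"),
)

CLINICAL_FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("age_y", "years", "clinical", "age at recording"),
    FeatureDef("sex", "0=female,1=male", "clinical", "sex"),
    FeatureDef("height_cm", "cm", "clinical", "body height"),
    FeatureDef("weight_kg", "kg", "clinical", "body weight"),
    FeatureDef("walking_stick", "0/1", "clinical", "walking-stick use"),
)

_EXCLUDED_FROM_STATS = {"nose", "r_eye", "l_eye", "r_ear", "l_ear", "midhip"}
STAT_KEYPOINTS: tuple[str, ...] = tuple(
    n for n in BODY25.names if n not in _EXCLUDED_FROM_STATS
)
STAT_SEGMENTS: tuple[str, ...] = ("seg1", "seg2")
STAT_KINDS: tuple[tuple[str, str, str], ...] = (
    ("mean_speed", "cm/s", "mean calibrated speed over the segment"),
    ("max_speed", "cm/s", "maximum calibrated speed over the segment"),
    ("vrange", "cm", "calibrated vertical excursion range over the segment"),
)


def _stat_features() -> tuple[FeatureDef, ...]:
    defs = []
    for kp in STAT_KEYPOINTS:
        for seg in STAT_SEGMENTS:
            for stat, unit, desc in STAT_KINDS:
                defs.append(
                    FeatureDef(
                        f"{kp}_{seg}_{stat}", unit, "stat",
                        f"{kp}: {desc} ({seg})",
                    )
                )
    return tuple(defs)


STAT_FEATURES = _stat_features()

_ALL: tuple[FeatureDef, ...] = NAMED_GAIT_FEATURES + STAT_FEATURES + CLINICAL_FEATURES

N_VIDEO_FEATURES = len(NAMED_GAIT_FEATURES) + len(STAT_FEATURES)
N_FEATURES = len(_ALL)

assert N_VIDEO_FEATURES == 123, N_VIDEO_FEATURES
assert N_FEATURES == 128, N_FEATURES


def feature_registry() -> pd.DataFrame:
    """The registry as a documented table (name, unit, kind, definition)."""
    return pd.DataFrame(
        [(f.name, f.unit, f.kind, f.definition) for f in _ALL],
        columns=["name", "unit", "kind", "definition"],
    )


def feature_names() -> tuple[str, ...]:
    return tuple(f.name for f in _ALL)


def video_feature_names() -> tuple[str, ...]:
    return tuple(f.name for f in _ALL if f.kind != "clinical")
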