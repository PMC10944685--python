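"""BODY_25 pose-keypoint schema and per-frame JSON time-series I/O.

The recording pipeline produces one JSON file per video frame in the
OpenPose dialect: a ``people`` list whose entries carry a flat
``pose_keypoints_2d`` array of 75 numbers, (x, y, confidence) for each of
25 body landmarks.  Image coordinates are pixels with the origin at the
top-left corner and y increasing downward; a confidence of 0 marks a
missing detection, in which case x and y are meaningless.

This module owns the 25-keypoint schema (label order, index lookup, and
the 12 lower-limb indices that the misdetection-correction stage acts on)
and reads, writes and summarises whole walking recordings as
:class:`KeypointSeries` objects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "BODY25",
    "KeypointSchema",
    "KeypointSeries",
    "KeypointParseError",
    "read_openpose_dir",
    "write_openpose_dir",
    "validate_series",
    "series_to_csv",
]

N_KEYPOINTS = 25

_BODY25_NAMES = (
    "nose",
    "neck",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "midhip",
    "r_hip",
    "r_knee",
    "r_ankle",
    "l_hip",
    "l_knee",
    "l_ankle",
    "r_eye",
    "l_eye",
    "r_ear",
    "l_ear",
    "l_bigtoe",
    "l_smalltoe",
    "l_heel",
    "r_bigtoe",
    "r_smalltoe",
    "r_heel",
)


class KeypointParseError(ValueError):
    """Raised when a per-frame JSON file cannot be interpreted."""


@dataclass(frozen=True)
class KeypointSchema:
    """Ordered landmark labels of the 25-keypoint body model.

    ``lower_limb_set`` holds the 12 indices of the bilateral hip, knee,
    ankle, big toe, small toe and heel -- the keypoints that foot
    left/right misdetection affects and that the correction stage deletes
    and re-interpolates in abnormal frames.
    """

    names: tuple[str, ...] = _BODY25_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != N_KEYPOINTS:
            raise ValueError(f"schema must have exactly {N_KEYPOINTS} keypoints")
        if len(set(self.names)) != N_KEYPOINTS:
            raise ValueError("keypoint labels must be unique")

    def index_of(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown keypoint label: {label!r}") from None

    @property
    def lower_limb_set(self) -> frozenset[int]:
        labels = (
            "l_hip", "l_knee", "l_ankle", "l_bigtoe", "l_smalltoe", "l_heel",
            "r_hip", "r_knee", "r_ankle", "r_bigtoe", "r_smalltoe", "r_heel",
        )
        return frozenset(self.index_of(l) for l in labels)

    def side(self, prefix: str, part: str) -> int:
        """Index of e.g. ``side('l', 'heel')``."""
        return self.index_of(f"{prefix}_{part}")


BODY25 = KeypointSchema()


@dataclass
class KeypointSeries:
    """A gapless sequence of per-frame 25-keypoint detections.

    ``xy`` has shape (n_frames, 25, 2) in pixels, ``conf`` shape
    (n_frames, 25) in [0, 1].  Frames are implicitly indexed 0..n-1.
    """

    xy: np.ndarray
    conf: np.ndarray
    fps: float = 30.0
    subject_id: str = ""
    schema: KeypointSchema = field(default_factory=lambda: BODY25)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError("xy must have shape (n_frames, 25, 2)")
        if self.conf.shape != self.xy.shape[:2]:
            raise ValueError("conf must have shape (n_frames, 25)")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if np.any((self.conf < 0) | (self.conf > 1)):
            raise ValueError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def copy(self) -> "KeypointSeries":
        return KeypointSeries(
            self.xy.copy(), self.conf.copy(), self.fps, self.subject_id, self.schema
        )

    def keypoint(self, label: str) -> np.ndarray:
        """(n_frames, 2) trajectory of one labelled keypoint."""
        return self.xy[:, self.schema.index_of(label), :]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeypointSeries):
            return NotImplemented
        return (
            self.fps == other.fps
            and self.subject_id == other.subject_id
            and self.xy.shape == other.xy.shape
            and bool(np.array_equal(self.xy, other.xy))
            and bool(np.array_equal(self.conf, other.conf))
        )


_FRAME_RE = re.compile(r"(\d+)\D*\.json$")


def _frame_number(path: Path) -> int:
    m = _FRAME_RE.search(path.name)
    if m is None:
        raise KeypointParseError(
            f"file name {path.name!r} has no trailing frame number before .json"
        )
    return int(m.group(1))


def _parse_frame(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (xy (25,2), conf (25,)) for the best-detected person in a frame.

    Multi-person frames resolve to the person with the highest total
    confidence (the recording protocol has a single patient in view);
    ties break toward the lower person index.  A frame with zero people
    is retained with all confidences 0.
    """
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise KeypointParseError(f"cannot parse frame file {path.name}: {exc}") from exc
    people = payload.get("people", [])
    best: np.ndarray | None = None
    best_total = -np.inf
    for person in people:
        flat = np.asarray(person.get("pose_keypoints_2d", ()), dtype=float)
        if flat.size != N_KEYPOINTS * 3:
            raise KeypointParseError(
                f"{path.name}: pose_keypoints_2d must hold {N_KEYPOINTS * 3} numbers, "
                f"got {flat.size}"
            )
        total = float(flat[2::3].sum())
        if total > best_total:
            best_total = total
            best = flat
    if best is None:
        return np.zeros((N_KEYPOINTS, 2)), np.zeros(N_KEYPOINTS)
    pts = best.reshape(N_KEYPOINTS, 3)
    return pts[:, :2].copy(), pts[:, 2].copy()


def read_openpose_dir(path: str | Path, fps: float = 30.0,
                      subject_id: str = "") -> KeypointSeries:
    """Read a directory of per-frame pose JSON files into a series.

    Files are ordered by the trailing integer in their names; the
    numbering may start anywhere but must be gapless.
    """
    path = Path(path)
    files = sorted(path.glob("*.json"), key=_frame_number)
    if not files:
        raise KeypointParseError(f"no frame JSON files found in {path}")
    numbers = [_frame_number(f) for f in files]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        raise KeypointParseError(
            f"frame numbers in {path} are not gapless/unique: got {numbers[:10]}..."
        )
    xy = np.empty((len(files), N_KEYPOINTS, 2))
    conf = np.empty((len(files), N_KEYPOINTS))
    for i, f in enumerate(files):
        xy[i], conf[i] = _parse_frame(f)
    return KeypointSeries(xy, conf, fps=fps, subject_id=subject_id or path.name)


def write_openpose_dir(series: KeypointSeries, path: str | Path,
                       prefix: str = "frame") -> None:
    """Write one JSON file per frame in the same dialect the reader consumes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(max(series.n_frames - 1, 0))))
    for i in range(series.n_frames):
        flat = np.concatenate(
            [series.xy[i], series.conf[i][:, None]], axis=1
        ).reshape(-1)
        payload = {
            "version": 1.3,
            "people": [{"person_id": [-1], "pose_keypoints_2d": flat.tolist()}],
        }
        (path / f"{prefix}_{i:0{width}d}.json").write_text(json.dumps(payload))


def validate_series(series: KeypointSeries) -> dict:
    """Pure summary report: frame count, duration, per-keypoint missingness."""
    missing = (series.conf == 0).mean(axis=0) if series.n_frames else np.ones(N_KEYPOINTS)
    return {
        "n_frames": series.n_frames,
        "duration_s": series.n_frames / series.fps,
        "fraction_missing_per_keypoint": {
            name: float(missing[i]) for i, name in enumerate(series.schema.names)
        },
    }


def series_to_csv(series: KeypointSeries, path: str | Path) -> None:
    """Flatten to long-format CSV (frame, keypoint, x, y, c) for debugging."""
    n, k = series.n_frames, N_KEYPOINTS
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), k),
            "keypoint": np.tile(np.asarray(series.schema.names), n),
            "x": series.xy[:, :, 0].reshape(-1),
            "y": series.xy[:, :, 1].reshape(-1),
            "c": series.conf.reshape(-1),
        }
    )
    df.to_csv(path, index=False)
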