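"""Anatomical joint-angle containers.

A :class:`JointAngleSet` holds one frame's angles in degrees: three
projection angles per shoulder and hip (spherical joints), one flexion
angle per elbow and knee (revolute joints), and the vertebral column's
twist (x) and bend (z).  Angles the geometry cannot resolve for a frame
(missing joints, gimbal poses) are *undefined*, stored as NaN and exposed
through ``defined`` — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANGLE_NAMES: tuple[str, ...] = (
    "shoulder_right_x", "shoulder_right_y", "shoulder_right_z",
    "shoulder_left_x", "shoulder_left_y", "shoulder_left_z",
    "elbow_right", "elbow_left",
    "hip_right_x", "hip_right_y", "hip_right_z",
    "hip_left_x", "hip_left_y", "hip_left_z",
    "knee_right", "knee_left",
    "spine_x", "spine_z",
)

#: default standing pose: arms by the side, legs together, facing the
#: sensor.  Shoulder/hip y = -90 deg is the limb hanging straight down
#: (on the Chest-to-Pelvis side of the lateral axis, hence negative under
#: the sign rule); elbows/knees straight at 180 deg.
REST_POSE: dict[str, float] = {
    "shoulder_right_x": 0.0, "shoulder_right_y": -90.0, "shoulder_right_z": 0.0,
    "shoulder_left_x": 0.0, "shoulder_left_y": -90.0, "shoulder_left_z": 0.0,
    "elbow_right": 180.0, "elbow_left": 180.0,
    "hip_right_x": 0.0, "hip_right_y": -90.0, "hip_right_z": 0.0,
    "hip_left_x": 0.0, "hip_left_y": -90.0, "hip_left_z": 0.0,
    "knee_right": 180.0, "knee_left": 180.0,
    "spine_x": 0.0, "spine_z": 0.0,
}


@dataclass
class JointAngleSet:
    """One frame's anatomical angles in degrees (NaN = undefined)."""

    angles: dict[str, float] = field(default_factory=lambda: dict(REST_POSE))

    def __post_init__(self) -> None:
        unknown = set(self.angles) - set(ANGLE_NAMES)
        if unknown:
            raise KeyError(f"unknown angle names {sorted(unknown)}")
        full = dict(REST_POSE)
        full.update(self.angles)
        self.angles = full

    def __getitem__(self, name: str) -> float:
        return self.angles[name]

    def __setitem__(self, name: str, value: float) -> None:
        if name not in ANGLE_NAMES:
            raise KeyError(name)
        self.angles[name] = float(value)

    def defined(self, name: str) -> bool:
        return bool(np.isfinite(self.angles[name]))

    def as_vector(self) -> np.ndarray:
        return np.array([self.angles[n] for n in ANGLE_NAMES])

    @classmethod
    def from_vector(cls, vec) -> "JointAngleSet":
        vec = np.asarray(vec, dtype=float)
        return cls(dict(zip(ANGLE_NAMES, vec)))


@dataclass
class AngleSeries:
    """Per-frame angle sets as a dense (n_frames, n_angles) array."""

    frame_indices: np.ndarray
    timestamps: np.ndarray
    names: list[str]
    values: np.ndarray  # degrees; NaN where undefined

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.frame_indices), len(self.names)):
            raise ValueError("values shape must be (n_frames, n_angles)")

    def __len__(self) -> int:
        return len(self.frame_indices)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def frame_set(self, i: int) -> JointAngleSet:
        return JointAngleSet(dict(zip(self.names, self.values[i])))

    @classmethod
    def from_sets(cls, frame_indices, timestamps,
                  sets: list[JointAngleSet]) -> "AngleSeries":
        values = np.stack([s.as_vector() for s in sets]) if sets else \
            np.empty((0, len(ANGLE_NAMES)))
        return cls(frame_indices, timestamps, list(ANGLE_NAMES), values)
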