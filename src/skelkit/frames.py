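"""Per-frame skeleton data, sequences, and segmented point clouds.

Coordinates are meters in the depth camera's frame: y points downward,
z points outward from the sensor toward the scene, x completes a
right-handed system.  A joint the tracker failed to resolve is reported as
exactly ``(0, 0, 0)`` and lives in the frame's ``missing`` set; the sentinel
is kept in the position array so the array always covers all 18 joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import N_JOINTS

#: fixed world "up": the camera y axis points downward.
GLOBAL_UP = np.array([0.0, -1.0, 0.0])

MISSING_SENTINEL = np.zeros(3)


class MissingJointError(ValueError):
    """An operation required a joint the tracker did not resolve."""


def _as_positions(positions) -> np.ndarray:
    arr = np.asarray(positions, dtype=float)
    if arr.shape != (N_JOINTS, 3):
        raise ValueError(f"positions must have shape ({N_JOINTS}, 3), got {arr.shape}")
    return arr


@dataclass
class SkeletonFrame:
    """One tracker frame: 18 joint positions plus the missing-joint mask."""

    frame_index: int
    timestamp: float
    positions: np.ndarray  # (18, 3) meters; missing joints hold (0,0,0)
    missing: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = _as_positions(self.positions)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        zero = np.all(self.positions == 0.0, axis=1)
        inferred = frozenset(np.nonzero(zero)[0].tolist())
        if self.missing is None:
            # tracker semantics: an exact (0,0,0) report means "not resolved"
            self.missing = inferred
        else:
            # an explicit mask is trusted: a joint genuinely observed at the
            # origin may be flagged non-missing by the caller
            self.missing = frozenset(int(j) for j in self.missing)
            for j in self.missing:
                self.positions[j] = 0.0

    def is_missing(self, joint_id: int) -> bool:
        return joint_id in self.missing

    def position(self, joint_id: int) -> np.ndarray:
        if joint_id in self.missing:
            raise MissingJointError(f"joint {joint_id} is missing in frame "
                                    f"{self.frame_index}")
        return self.positions[joint_id]

    def copy(self) -> "SkeletonFrame":
        return SkeletonFrame(self.frame_index, self.timestamp,
                             self.positions.copy(), self.missing)


@dataclass
class SkeletonSequence:
    """Ordered tracker frames at a nominal frame rate."""

    frames: list[SkeletonFrame]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")
        ts = [f.timestamp for f in self.frames]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be nondecreasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> SkeletonFrame:
        return self.frames[i]

    def positions_array(self) -> np.ndarray:
        """(n_frames, 18, 3) stacked positions (missing joints hold zeros)."""
        return np.stack([f.positions for f in self.frames])

    def missing_mask(self) -> np.ndarray:
        """(n_frames, 18) boolean mask of missing joints."""
        mask = np.zeros((len(self.frames), N_JOINTS), dtype=bool)
        for i, f in enumerate(self.frames):
            mask[i, list(f.missing)] = True
        return mask

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence([f.copy() for f in self.frames], self.frame_rate)


@dataclass
class PointCloudSegment:
    """Labeled 3D point set attributed to a joint/limb neighborhood."""

    label: str
    points: np.ndarray  # (n, 3) meters, camera frame

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


def limb_vector(frame: SkeletonFrame, joint_id: int, topology) -> np.ndarray:
    """Child-minus-parent displacement of ``joint_id``'s limb, in meters.

    The root (nose) has no limb; both endpoints must be observed.
    """
    parent = topology.parent[joint_id]
    if parent is None:
        raise ValueError("the root joint has no limb vector")
    return frame.position(joint_id) - frame.position(parent)
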