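"""Point-cloud-assisted repair of missing and depth-noisy joints.

The compensation algorithm works from a reference frame captured while
the subject holds a default standing pose:

1. **Initialization** — among the first ``window`` frames in which all 18
   joints are observed, pick the one whose 18 depth (z) coordinates have
   the smallest standard deviation; compute the child-parent distance of
   every limb there.  These limb distances are treated as rigid.
2. **Per-frame validation** — joints are processed in ascending joint-ID
   order (the nose first), so a child is always validated against its
   already-corrected parent.  A joint is kept iff it is observed, moved
   no more than ``displacement_bound`` since the corrected previous
   frame, and sits within ``[lower, upper] x limb distance`` of its
   corrected parent.
3. **Repair** — a rejected or missing joint is re-estimated from the
   frame's segmented point cloud: the candidate is the cloud point
   nearest to the joint's corrected previous-frame position whose
   distance to the corrected parent lies in the limb interval (the root
   joint searches unconstrained).  When the tracker did report a
   position, the candidate is averaged with it — provided the midpoint
   still satisfies the limb interval — either when the two agree within
   the displacement bound or when averaging moves the estimate closer to
   the previous frame.  If no cloud point qualifies, the previous
   position is carried forward and the joint is flagged ``fallback``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import PointCloudSegment, SkeletonFrame, SkeletonSequence
from .topology import DEFAULT_TOPOLOGY, N_JOINTS, SkeletonTopology


class InitializationError(RuntimeError):
    """No fully-observed frame was found in the initialization window.

    Capture a longer segment of the default standing pose facing the
    sensor so that every joint is visible at least once."""


@dataclass(frozen=True)
class EstimationParams:
    """Bounds of the validation/repair rules.

    ``lower_bound_frac``/``upper_bound_frac`` scale each limb's reference
    distance into the acceptance interval; ``displacement_bound`` caps
    per-frame joint travel in meters; ``window`` is the number of initial
    frames searched for the reference frame."""

    lower_bound_frac: float = 0.8
    upper_bound_frac: float = 1.2
    displacement_bound: float = 0.25
    window: int = 30
    drop_before_reference: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_bound_frac <= 1.0 <= self.upper_bound_frac:
            raise ValueError("need 0 <= lower_bound_frac <= 1 <= upper_bound_frac")
        if self.displacement_bound <= 0:
            raise ValueError("displacement_bound must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class LimbDistanceTable:
    """Reference child-parent distances learned at the reference frame."""

    distance: dict[tuple[int, int], float]
    reference_frame_index: int

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.distance.values()):
            raise ValueError("limb distances must be positive")

    def for_child(self, joint_id: int) -> float:
        for (child, _parent), d in self.distance.items():
            if child == joint_id:
                return d
        raise KeyError(f"no limb distance for joint {joint_id}")


@dataclass
class RepairRecord:
    frame_index: int
    joint_id: int
    action: str  # kept | repaired | fallback


def select_reference_frame(sequence: SkeletonSequence, window: int) -> int:
    """Index (into ``sequence.frames``) of the initialization frame.

    Among fully-observed frames within the first ``window`` frames,
    returns the one minimizing the standard deviation of the 18 depth
    coordinates; ties go to the earliest frame.
    """
    best = None
    best_sd = np.inf
    for i, frame in enumerate(sequence.frames[:window]):
        if frame.missing:
            continue
        sd = float(np.std(frame.positions[:, 2]))
        if sd < best_sd:
            best, best_sd = i, sd
    if best is None:
        raise InitializationError(
            f"no fully-observed frame in the first {window} frames; capture a "
            "longer segment of the default standing pose")
    return best


def compute_limb_distances(frame: SkeletonFrame,
                           topology: SkeletonTopology = DEFAULT_TOPOLOGY,
                           ) -> LimbDistanceTable:
    """Euclidean child-parent distance of every limb; 17 entries."""
    distance = {}
    for child, parent in topology.limbs:
        distance[(child, parent)] = float(np.linalg.norm(
            frame.position(child) - frame.position(parent)))
    return LimbDistanceTable(distance, frame.frame_index)


def validate_joint(current_pos, previous_pos, limb_dist_to_parent,
                   current_parent_pos, params: EstimationParams) -> bool:
    """Accept a tracked joint position for the current frame.

    ``current_pos`` is None for a missing joint (always rejected).  The
    limb check is skipped for the root (``limb_dist_to_parent`` None).
    """
    if current_pos is None:
        return False
    current_pos = np.asarray(current_pos, dtype=float)
    if np.linalg.norm(current_pos - previous_pos) > params.displacement_bound:
        return False
    if limb_dist_to_parent is not None:
        d = np.linalg.norm(current_pos - np.asarray(current_parent_pos, float))
        if not (params.lower_bound_frac * limb_dist_to_parent
                <= d <= params.upper_bound_frac * limb_dist_to_parent):
            return False
    return True


def _nearest_valid_point(points: np.ndarray, previous_pos, parent_pos,
                         limb_dist, params: EstimationParams):
    """Cloud point nearest to ``previous_pos`` among those at limb
    distance (within the interval) from the parent; ties take the lowest
    point index.  ``limb_dist`` None lifts the constraint (root)."""
    if len(points) == 0:
        return None
    if limb_dist is None:
        ok = np.ones(len(points), dtype=bool)
    else:
        dp = np.linalg.norm(points - np.asarray(parent_pos, float), axis=1)
        ok = ((dp >= params.lower_bound_frac * limb_dist)
              & (dp <= params.upper_bound_frac * limb_dist))
    if not ok.any():
        return None
    idx = np.nonzero(ok)[0]
    d = np.linalg.norm(points[idx] - np.asarray(previous_pos, float), axis=1)
    return points[idx[np.argmin(d)]].copy()


def repair_joint(joint_id, previous_pos, current_pos_or_missing, parent_pos,
                 limb_dist, cloud: PointCloudSegment | np.ndarray,
                 params: EstimationParams):
    """Re-estimate one joint from its segmented point cloud.

    Returns ``(position, action)`` with action ``repaired`` or
    ``fallback``.  See the module docstring for the candidate/mean-update
    rules; the mean update only applies when the tracker reported a
    position, and only if the midpoint itself keeps the limb interval.
    """
    points = cloud.points if isinstance(cloud, PointCloudSegment) else \
        np.asarray(cloud, dtype=float)
    previous_pos = np.asarray(previous_pos, dtype=float)
    candidate = _nearest_valid_point(points, previous_pos, parent_pos,
                                     limb_dist, params)
    if candidate is None:
        return previous_pos.copy(), "fallback"
    if current_pos_or_missing is None:
        return candidate, "repaired"
    current = np.asarray(current_pos_or_missing, dtype=float)
    midpoint = 0.5 * (candidate + current)

    def limb_ok(pos):
        if limb_dist is None:
            return True
        d = np.linalg.norm(pos - np.asarray(parent_pos, float))
        return (params.lower_bound_frac * limb_dist
                <= d <= params.upper_bound_frac * limb_dist)

    take_mean = (np.linalg.norm(candidate - current) <= params.displacement_bound
                 or np.linalg.norm(midpoint - previous_pos)
                 < np.linalg.norm(candidate - previous_pos))
    if take_mean and limb_ok(midpoint):
        return midpoint, "repaired"
    return candidate, "repaired"


def _clouds_as_dict(clouds) -> dict[str, np.ndarray]:
    if clouds is None:
        return {}
    if isinstance(clouds, dict):
        items = clouds.items()
    else:
        items = ((seg.label, seg) for seg in clouds)
    out = {}
    for label, seg in items:
        pts = seg.points if isinstance(seg, PointCloudSegment) else \
            np.asarray(seg, dtype=float)
        out[str(label)] = pts
    return out


def _cloud_for_joint(joint_id: int, cloud_map: dict[str, np.ndarray],
                     topology: SkeletonTopology) -> np.ndarray:
    """Joint -> associated segmented cloud.

    Each non-root joint owns its limb's segment (labeled by the child
    joint's name or id).  The root pools the segments of the limbs
    incident to it (chest and head limbs) since it has no limb of its own.
    """
    if topology.parent[joint_id] is not None:
        for key in (topology.name(joint_id), str(joint_id)):
            if key in cloud_map:
                return cloud_map[key]
        return np.empty((0, 3))
    parts = [cloud_map[key]
             for child, parent in topology.limbs if parent == joint_id
             for key in (topology.name(child), str(child)) if key in cloud_map]
    return np.vstack(parts) if parts else np.empty((0, 3))


def process_sequence(sequence: SkeletonSequence, clouds_per_frame,
                     topology: SkeletonTopology = DEFAULT_TOPOLOGY,
                     params: EstimationParams = EstimationParams(),
                     ) -> tuple[SkeletonSequence, list[RepairRecord]]:
    """Run the full compensation algorithm over a sequence.

    ``clouds_per_frame`` maps each frame's position in the sequence (or
    its frame_index) to that frame's segmented clouds (dict label ->
    cloud, or list of :class:`PointCloudSegment`); frames without clouds
    fall back to carrying joints forward when repair is needed.

    Returns the corrected sequence (starting at the reference frame when
    ``drop_before_reference``) and the per-joint repair log.
    """
    ref = select_reference_frame(sequence, params.window)
    table = compute_limb_distances(sequence[ref], topology)

    def frame_clouds(pos_in_seq: int, frame: SkeletonFrame):
        if clouds_per_frame is None:
            return {}
        src = None
        if pos_in_seq in clouds_per_frame:
            src = clouds_per_frame[pos_in_seq]
        elif frame.frame_index in clouds_per_frame:
            src = clouds_per_frame[frame.frame_index]
        return _clouds_as_dict(src)

    log: list[RepairRecord] = []
    out_frames: dict[int, SkeletonFrame] = {}
    ref_frame = sequence[ref].copy()
    out_frames[ref] = ref_frame
    for j in range(N_JOINTS):
        log.append(RepairRecord(ref_frame.frame_index, j, "kept"))

    def process_one(i: int, prev_corrected: SkeletonFrame) -> SkeletonFrame:
        raw = sequence[i]
        cloud_map = frame_clouds(i, raw)
        new_pos = np.empty((N_JOINTS, 3))
        flagged: set[int] = set()
        for j in range(N_JOINTS):
            parent = topology.parent[j]
            limb_dist = None if parent is None else table.distance[(j, parent)]
            parent_pos = None if parent is None else new_pos[parent]
            current = None if raw.is_missing(j) else raw.positions[j]
            prev = prev_corrected.positions[j]
            if validate_joint(current, prev, limb_dist, parent_pos, params):
                new_pos[j] = current
                log.append(RepairRecord(raw.frame_index, j, "kept"))
                continue
            pos, action = repair_joint(
                j, prev, current, parent_pos, limb_dist,
                _cloud_for_joint(j, cloud_map, topology), params)
            new_pos[j] = pos
            if action == "fallback":
                flagged.add(j)
            log.append(RepairRecord(raw.frame_index, j, action))
        return SkeletonFrame(raw.frame_index, raw.timestamp, new_pos,
                             missing=frozenset())

    prev = ref_frame
    for i in range(ref + 1, len(sequence)):
        prev = process_one(i, prev)
        out_frames[i] = prev
    if not params.drop_before_reference:
        prev = ref_frame
        for i in range(ref - 1, -1, -1):
            prev = process_one(i, prev)
            out_frames[i] = prev
    ordered = [out_frames[i] for i in sorted(out_frames)]
    log.sort(key=lambda r: (r.frame_index, r.joint_id))
    return SkeletonSequence(ordered, frame_rate=sequence.frame_rate), log
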