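"""Ground-truth articulated motion and sensor-noise emulation.

Real captures from RGB-D skeleton trackers show three failure modes: the
x,y image-plane coordinates vary smoothly while the depth (z) coordinate
of each joint carries high-variance noise; individual joints drop out as
exact ``(0,0,0)`` reports during self-occlusion; and occasionally whole
frames lose every joint.  This module builds noiseless skeleton streams
by forward kinematics from known joint angles, then corrupts them with
exactly that phenomenology, and emits per-limb point clouds like the
segmented clouds a depth sensor provides — so the estimation and
angle-extraction stages can be tested against known ground truth.

The noise model is zero-mean Gaussian, independent per joint per frame,
with the depth standard deviation decoupled from (and much larger than)
the image-plane one.  Dropout is i.i.d. Bernoulli per joint, plus an
optional burst mode that drops all joints for a run of consecutive
frames.  Point clouds are uniform in a capsule around each limb segment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .angles import ANGLE_NAMES, AngleSeries, JointAngleSet, REST_POSE
from .frames import GLOBAL_UP, PointCloudSegment, SkeletonFrame, SkeletonSequence
from .geometry import unit
from .kinematics import (AnatomicalVectors, _hip_frame,
                         _shoulder_frame, twist_references)
from .topology import DEFAULT_TOPOLOGY, N_JOINTS, NAME_TO_ID

_J = NAME_TO_ID


@dataclass(frozen=True)
class BodyDimensions:
    """Subject anthropometry, meters.  Bilateral limbs are equal."""

    shoulder_width: float = 0.36
    hip_width: float = 0.30
    torso_length: float = 0.45   # pelvis (hip midpoint) to chest
    neck_length: float = 0.25    # chest to nose
    upper_arm: float = 0.30
    forearm: float = 0.27
    thigh: float = 0.42
    shank: float = 0.41
    eye_offset: tuple[float, float, float] = (0.035, 0.03, 0.0)
    ear_offset: tuple[float, float, float] = (0.08, 0.02, -0.05)

    def __post_init__(self) -> None:
        for name in ("shoulder_width", "hip_width", "torso_length",
                     "neck_length", "upper_arm", "forearm", "thigh", "shank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def limb_lengths(self) -> dict[tuple[int, int], float]:
        """Reference child-parent distance per limb of the default topology."""
        eye = float(np.linalg.norm(self.eye_offset))
        ear = float(np.linalg.norm(self.ear_offset))
        chest_hip = math.hypot(self.torso_length, self.hip_width / 2)
        d = {
            (1, 0): self.neck_length,
            (2, 1): self.shoulder_width / 2, (5, 1): self.shoulder_width / 2,
            (3, 2): self.upper_arm, (6, 5): self.upper_arm,
            (4, 3): self.forearm, (7, 6): self.forearm,
            (8, 1): chest_hip, (11, 1): chest_hip,
            (9, 8): self.thigh, (12, 11): self.thigh,
            (10, 9): self.shank, (13, 12): self.shank,
            (14, 0): eye, (15, 0): eye,
            (16, 0): ear, (17, 0): ear,
        }
        return d


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = unit(axis)
    th = math.radians(angle_deg)
    return (v * math.cos(th) + np.cross(a, v) * math.sin(th)
            + a * np.dot(a, v) * (1 - math.cos(th)))


def forward_kinematics(angle_set: JointAngleSet, dims: BodyDimensions,
                       pelvis_position=(0.0, 0.0, 2.0),
                       body_yaw_deg: float = 0.0,
                       global_up: np.ndarray = GLOBAL_UP,
                       frame_index: int = 0,
                       timestamp: float = 0.0) -> SkeletonFrame:
    """Realize a complete angle set as joint positions.

    The subject faces the negative camera z axis when ``body_yaw_deg`` is
    zero (hips level, hip line horizontal).  The construction inverts the
    angle extraction exactly: for non-singular angle sets,
    :func:`~skelkit.kinematics.extract_frame_angles` on the result
    recovers the inputs.  Elbow/knee angles outside [0, 180] are clamped
    with a warning; spherical y/z pairs must be hemisphere-consistent
    (see :meth:`_BallFrame.apply_yz`).
    """
    ang = dict(angle_set.angles)
    bad = [n for n, v in ang.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"angle set incomplete: undefined {sorted(bad)}")
    for name in ("elbow_right", "elbow_left", "knee_right", "knee_left"):
        if not 0.0 <= ang[name] <= 180.0:
            warnings.warn(f"{name}={ang[name]:.1f} outside [0, 180]; clamped",
                          stacklevel=2)
            ang[name] = float(np.clip(ang[name], 0.0, 180.0))

    up = unit(global_up)
    pelvis = np.asarray(pelvis_position, dtype=float)
    # base frame: hip line horizontal, subject facing -z at zero yaw
    h_dir = _rotate_about(np.array([1.0, 0.0, 0.0]), up, body_yaw_deg)
    r2l_hip = h_dir  # right hip -> left hip direction
    fwd_low = unit(np.cross(r2l_hip, up))

    pos = np.zeros((N_JOINTS, 3))
    r_hip = pelvis - 0.5 * dims.hip_width * h_dir
    l_hip = pelvis + 0.5 * dims.hip_width * h_dir
    pos[_J["right_hip"]] = r_hip
    pos[_J["left_hip"]] = l_hip

    # torso: bend in the hips' sagittal plane, twist about global up
    sz, sx = ang["spine_z"], ang["spine_x"]
    p2c_dir = math.cos(math.radians(sz)) * up + math.sin(math.radians(sz)) * fwd_low
    chest = pelvis + dims.torso_length * p2c_dir
    pos[_J["chest"]] = chest
    r2l_sh_dir = _rotate_about(h_dir, up, sx)
    r_sh = chest - 0.5 * dims.shoulder_width * r2l_sh_dir
    l_sh = chest + 0.5 * dims.shoulder_width * r2l_sh_dir
    pos[_J["right_shoulder"]] = r_sh
    pos[_J["left_shoulder"]] = l_sh

    nose = chest + dims.neck_length * p2c_dir
    pos[_J["nose"]] = nose

    # head block: fixed offsets in the head's orthonormal frame
    l2r_sh = r_sh - l_sh
    c2p = pelvis - chest
    n_u = unit(np.cross(l2r_sh, c2p))     # forward facing, upper body
    lat_r = unit(l2r_sh)                  # right-lateral
    head_up = -unit(np.cross(n_u, lat_r))
    ex, ey, ez = dims.eye_offset
    ax, ay, az = dims.ear_offset
    pos[_J["right_eye"]] = nose + ex * lat_r + ey * head_up + ez * n_u
    pos[_J["left_eye"]] = nose - ex * lat_r + ey * head_up + ez * n_u
    pos[_J["right_ear"]] = nose + ax * lat_r + ay * head_up + az * n_u
    pos[_J["left_ear"]] = nose - ax * lat_r + ay * head_up + az * n_u

    vec = AnatomicalVectors(
        pelvis=pelvis, left_to_right_shoulder=l2r_sh, chest_to_pelvis=c2p,
        pelvis_to_chest=-c2p, right_to_left_hip=l_hip - r_hip, global_up=up,
        forward_facing=np.cross(l2r_sh, c2p),
        forward_facing_lower=np.cross(l_hip - r_hip, up),
    )

    for side in ("right", "left"):
        bf = _shoulder_frame(vec, side)
        u = bf.apply_yz(ang[f"shoulder_{side}_y"], ang[f"shoulder_{side}_z"])
        sh = pos[_J[f"{side}_shoulder"]]
        elbow = sh + dims.upper_arm * u
        pos[_J[f"{side}_elbow"]] = elbow
        eps = math.radians(ang[f"elbow_{side}"])
        e2w = -math.cos(eps) * u
        if abs(math.sin(eps)) > 1e-12:
            ref, cr = twist_references(vec.forward_facing, u, "ref_first")
            xr = math.radians(ang[f"shoulder_{side}_x"])
            w = math.cos(xr) * ref - math.sin(xr) * cr
            e2w = e2w + math.sin(eps) * w
        pos[_J[f"{side}_wrist"]] = elbow + dims.forearm * unit(e2w)

        bh = _hip_frame(vec, side)
        t = bh.apply_yz(ang[f"hip_{side}_y"], ang[f"hip_{side}_z"])
        hip = pos[_J[f"{side}_hip"]]
        knee = hip + dims.thigh * t
        pos[_J[f"{side}_knee"]] = knee
        kap = math.radians(ang[f"knee_{side}"])
        k2a = -math.cos(kap) * t
        if abs(math.sin(kap)) > 1e-12:
            ref, cr = twist_references(-vec.forward_facing_lower, t, "limb_first")
            xr = math.radians(ang[f"hip_{side}_x"])
            w = math.cos(xr) * ref - math.sin(xr) * cr
            k2a = k2a + math.sin(kap) * w
        pos[_J[f"{side}_ankle"]] = knee + dims.shank * unit(k2a)

    return SkeletonFrame(frame_index, timestamp, pos, missing=frozenset())


# ---------------------------------------------------------------------------
# trajectories and motion generation

#: a 10 s capture: one second holding the default standing pose (the
#: initialization protocol), then the right arm reaches out (abduction +
#: elbow flexion + a touch of humeral rotation and forward bend) and
#: returns — the shape of a reach-for-an-object task.
DEFAULT_TRAJECTORIES: dict[str, list[tuple[float, float]]] = {
    "shoulder_right_y": [(0, -90), (1, -90), (3, -25), (6, -25), (8, -90)],
    "elbow_right": [(0, 180), (1, 180), (3, 120), (6, 120), (8, 180)],
    "shoulder_right_x": [(0, 0), (3, 0), (4, 40), (5.5, 0), (8, 0)],
    "spine_z": [(0, 0), (1, 0), (4, 10), (7, 0)],
}


def evaluate_trajectory(traj, t: float) -> float:
    """Evaluate a trajectory spec: scalar, callable of time, or a
    keyframe list of (time_s, degrees) pairs (piecewise linear, clamped
    at the ends)."""
    if callable(traj):
        return float(traj(t))
    if np.isscalar(traj):
        return float(traj)
    kf = sorted((float(a), float(b)) for a, b in traj)
    times = [a for a, _ in kf]
    vals = [b for _, b in kf]
    return float(np.interp(t, times, vals))


@dataclass
class MotionConfig:
    """Generator settings: study conditions for the synthetic captures."""

    n_frames: int = 300
    frame_rate: float = 30.0
    angle_trajectories: dict = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES))
    depth_noise_sd: float = 0.05    # meters, per-joint z noise
    xy_noise_sd: float = 0.005      # meters, per-joint x/y noise
    dropout_prob: float = 0.1       # per joint per frame
    cloud_points_per_limb: int = 400
    cloud_radius: float = 0.04      # meters, capsule radius
    seed: int = 0
    calibration_frames: int = 30    # dropout-free initial standing segment
    burst_length: int = 0           # whole-frame dropout run length
    burst_starts: tuple[int, ...] = ()
    pelvis_position: tuple[float, float, float] = (0.0, 0.0, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.depth_noise_sd < 0 or self.xy_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_frames < 1 or self.frame_rate <= 0:
            raise ValueError("need n_frames >= 1 and frame_rate > 0")
        if self.cloud_radius < 0 or self.cloud_points_per_limb < 0:
            raise ValueError("cloud parameters must be >= 0")
        unknown = set(self.angle_trajectories) - set(ANGLE_NAMES)
        if unknown:
            raise ValueError(f"unknown trajectory angles {sorted(unknown)}")


@dataclass
class GroundTruth:
    """The generator's truth: input angles and the noiseless skeleton."""

    angles: AngleSeries
    clean_frames: SkeletonSequence


def generate_motion(config: MotionConfig,
                    dims: BodyDimensions | None = None) -> GroundTruth:
    """Forward-kinematic motion from the configured angle trajectories."""
    dims = dims or BodyDimensions()
    sets = []
    frames = []
    for i in range(config.n_frames):
        t = i / config.frame_rate
        ang = dict(REST_POSE)
        for name, traj in config.angle_trajectories.items():
            ang[name] = evaluate_trajectory(traj, t)
        aset = JointAngleSet(ang)
        sets.append(aset)
        frames.append(forward_kinematics(
            aset, dims, pelvis_position=config.pelvis_position,
            frame_index=i, timestamp=t))
    return GroundTruth(
        angles=AngleSeries.from_sets(list(range(config.n_frames)),
                                     [f.timestamp for f in frames], sets),
        clean_frames=SkeletonSequence(frames, frame_rate=config.frame_rate),
    )


def corrupt_sequence(clean: SkeletonSequence, config: MotionConfig,
                     seed: int | None = None) -> SkeletonSequence:
    """Apply the tracker's noise phenomenology to a noiseless sequence.

    Per joint per frame: Gaussian noise (z sd ``depth_noise_sd``, x/y sd
    ``xy_noise_sd``) and Bernoulli dropout to the ``(0,0,0)`` sentinel.
    Dropout (including bursts) is suppressed during the first
    ``calibration_frames`` frames.  Deterministic given the seed.
    """
    if any(f.missing for f in clean):
        raise ValueError("corrupt_sequence expects a fully-observed sequence")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(clean)
    noise = np.zeros((n, N_JOINTS, 3))
    noise[:, :, 0] = rng.normal(0.0, config.xy_noise_sd, (n, N_JOINTS))
    noise[:, :, 1] = rng.normal(0.0, config.xy_noise_sd, (n, N_JOINTS))
    noise[:, :, 2] = rng.normal(0.0, config.depth_noise_sd, (n, N_JOINTS))
    drop = rng.random((n, N_JOINTS)) < config.dropout_prob
    drop[: config.calibration_frames] = False
    for start in config.burst_starts:
        stop = start + config.burst_length
        drop[max(start, config.calibration_frames): stop] = True
    out = []
    for i, f in enumerate(clean):
        p = f.positions + noise[i]
        p[drop[i]] = 0.0
        out.append(SkeletonFrame(f.frame_index, f.timestamp, p,
                                 missing=frozenset(np.nonzero(drop[i])[0].tolist())))
    return SkeletonSequence(out, frame_rate=clean.frame_rate)


# ---------------------------------------------------------------------------
# per-limb point clouds

def _capsule_samples(rng, p0, p1, radius, n):
    """Uniform samples in the capsule of given radius around segment p0-p1."""
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    a_hat = axis / length if length > 0 else np.array([0.0, 0.0, 1.0])
    if radius <= 0.0:
        t = rng.random(n)
        return p0 + np.outer(t, axis)
    # volume split between the cylinder body and the two end half-balls
    p_cyl = length / (length + 4.0 * radius / 3.0)
    in_cyl = rng.random(n) < p_cyl
    pts = np.empty((n, 3))
    # orthonormal frame perpendicular to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, a_hat)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(a_hat, helper))
    e2 = np.cross(a_hat, e1)
    k = int(np.count_nonzero(in_cyl))
    if k:
        t = rng.random(k) * length
        rho = radius * np.sqrt(rng.random(k))
        phi = rng.random(k) * 2.0 * np.pi
        pts[in_cyl] = (p0 + np.outer(t, a_hat)
                       + np.outer(rho * np.cos(phi), e1)
                       + np.outer(rho * np.sin(phi), e2))
    m = n - k
    if m:
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        off = v * (radius * rng.random(m) ** (1.0 / 3.0))[:, None]
        ends = np.where(off @ a_hat > 0, 1.0, 0.0)
        pts[~in_cyl] = p0 + np.outer(ends, axis) + off
    return pts


def sample_point_clouds(frame: SkeletonFrame, dims: BodyDimensions,
                        config: MotionConfig,
                        seed: int | None = None) -> list[PointCloudSegment]:
    """Segmented per-limb clouds around the frame's true limb segments.

    Clouds reflect the actual body surface, so they are sampled from the
    *clean* frame even when the tracker drops the joint.  One segment per
    limb, labeled by the child joint's name; ``cloud_points_per_limb``
    points uniform within a capsule of ``cloud_radius`` around the
    segment.  Deterministic given the seed (derived from the config seed
    and frame index by default).
    """
    if frame.missing:
        raise ValueError("point clouds are sampled from fully-observed frames")
    rng = np.random.default_rng(
        (config.seed, frame.frame_index) if seed is None else seed)
    topo = DEFAULT_TOPOLOGY
    segments = []
    for child, parent in topo.limbs:
        pts = _capsule_samples(rng, frame.positions[parent],
                               frame.positions[child], config.cloud_radius,
                               config.cloud_points_per_limb)
        segments.append(PointCloudSegment(topo.name(child), pts))
    return segments


# ---------------------------------------------------------------------------
# random pose sampling for round-trip checks

def sample_nonsingular_angles(rng: np.random.Generator,
                              spine: bool = True) -> JointAngleSet:
    """Random angle set away from the gimbal poses of the extraction.

    Limb y/z projections stay at least 5 deg from their singular axes,
    elbows/knees at least 15 deg from straight/folded, and shoulder y is
    rejected until the hemisphere condition holds against the sampled
    spine twist+bend (which skews the shoulder frame).
    """
    ang = dict(REST_POSE)
    sx = float(rng.uniform(-80, 80)) if spine else 0.0
    szn = float(rng.uniform(-60, 60)) if spine else 0.0
    ang["spine_x"], ang["spine_z"] = sx, szn
    # lateral component of chest->pelvis in each shoulder frame
    p_right = -math.sin(math.radians(szn)) * math.sin(math.radians(sx))
    for side, p in (("right", p_right), ("left", -p_right)):
        q = math.sqrt(max(1.0 - p * p, 0.0))
        while True:
            y = float(rng.uniform(-85, 85))
            if q * math.cos(math.radians(y)) + p * math.sin(math.radians(y)) > 0.1:
                break
        ang[f"shoulder_{side}_y"] = y
        ang[f"shoulder_{side}_z"] = float(rng.uniform(-85, 85))
        ang[f"shoulder_{side}_x"] = float(rng.uniform(-175, 175))
        ang[f"elbow_{side}"] = float(rng.uniform(15, 165))
        ang[f"hip_{side}_y"] = float(rng.uniform(-85, 85))
        ang[f"hip_{side}_z"] = float(rng.uniform(-85, 85))
        ang[f"hip_{side}_x"] = float(rng.uniform(-175, 175))
        ang[f"knee_{side}"] = float(rng.uniform(15, 165))
    return JointAngleSet(ang)
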