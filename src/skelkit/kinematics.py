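"""Anatomical joint angles from skeleton coordinates.

The virtual-human model treats shoulders, hips and the spine-to-hip link
as spherical joints and elbows/knees as revolute hinges.  Each spherical
joint's rotations are resolved by projecting limb vectors onto reference
planes built from a handful of named body vectors:

* ``Left to Right Shoulder`` and ``Chest to Pelvis`` (the pelvis is the
  synthetic joint at the midpoint of the two hips); their cross product is
  the upper body's ``Forward Facing`` vector.
* ``Right to Left Hip`` crossed with ``Global Up`` (the negated camera y
  axis) gives the lower body's ``Forward Facing`` vector.

For each rotation, the limb vector is projected onto a plane, compared
with an in-plane reference vector, and the sign of the resulting angle is
fixed by which side of the reference the projection falls on (the
"betweenness" rule).  Sign conventions:

* shoulder/hip **y** (abduction): 0 at the side-lateral direction,
  negative toward Chest-to-Pelvis / downward — the hanging limb reads
  -90 deg, the overhead arm +90 deg.
* shoulder/hip **z** (flexion): 0 at the lateral direction in the
  transverse plane, negative toward Forward Facing.
* shoulder/hip **x** (axial rotation, read off the distal segment):
  0 when the projected forearm/shank aligns with the (Backwards-)Forward
  Facing projection, negative on the Cross-Elbow / Cross-Knee side.
* spine **x** (twist): right-handed about Global Up, shoulders vs hips.
* spine **z** (bend): 0 upright, positive bending toward Forward Facing.

Angles are degrees.  Poses where a projection degenerates (limb parallel
to a plane normal) have no defined angle; strict operations raise
:class:`~skelkit.geometry.SingularityError`, sequence extraction emits
NaN flagged undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .angles import ANGLE_NAMES, AngleSeries, JointAngleSet
from .frames import GLOBAL_UP, MissingJointError, SkeletonFrame, SkeletonSequence
from .geometry import SINGULARITY_TOL, SingularityError, project_onto_plane, unit
from .topology import NAME_TO_ID

_R = NAME_TO_ID  # joint name -> id shortcuts

_SIDES = ("right", "left")


def _deg_atan2(y: float, x: float) -> float:
    return math.degrees(math.atan2(y, x))


@dataclass
class AnatomicalVectors:
    """The named body vectors the angle constructions are built from."""

    pelvis: np.ndarray
    left_to_right_shoulder: np.ndarray
    chest_to_pelvis: np.ndarray
    pelvis_to_chest: np.ndarray
    right_to_left_hip: np.ndarray
    global_up: np.ndarray
    forward_facing: np.ndarray        # upper body: cross(l2r shoulder, chest->pelvis)
    forward_facing_lower: np.ndarray  # lower body: cross(r2l hip, global up)


def anatomical_vectors(frame: SkeletonFrame,
                       global_up: np.ndarray = GLOBAL_UP) -> AnatomicalVectors:
    """Compute the shared reference vectors for one frame.

    Requires both shoulders, both hips and the chest to be observed.
    """
    r_sh = frame.position(_R["right_shoulder"])
    l_sh = frame.position(_R["left_shoulder"])
    chest = frame.position(_R["chest"])
    r_hip = frame.position(_R["right_hip"])
    l_hip = frame.position(_R["left_hip"])
    pelvis = 0.5 * (r_hip + l_hip)
    l2r = r_sh - l_sh
    c2p = pelvis - chest
    r2l_hip = l_hip - r_hip
    up = np.asarray(global_up, dtype=float)
    return AnatomicalVectors(
        pelvis=pelvis,
        left_to_right_shoulder=l2r,
        chest_to_pelvis=c2p,
        pelvis_to_chest=-c2p,
        right_to_left_hip=r2l_hip,
        global_up=up,
        forward_facing=np.cross(l2r, c2p),
        forward_facing_lower=np.cross(r2l_hip, up),
    )


# ---------------------------------------------------------------------------
# spherical-joint plane frames

@dataclass
class _BallFrame:
    """Orthonormal working frame for one spherical joint.

    ``lateral`` is the side's outward direction along the shoulder/hip
    line, ``down`` the in-plane component of the negative-sign reference
    (Chest-to-Pelvis for shoulders, -Global-Up for hips), ``forward`` the
    unit Forward Facing normal.  (lateral, down) spans the abduction (y)
    plane; the flexion (z) plane is perpendicular to the raw down
    reference and carries (lateral_z, forward).
    """

    lateral: np.ndarray
    down: np.ndarray
    forward: np.ndarray
    down_raw: np.ndarray      # unnormalized sign reference (c2p or -up)
    lateral_z: np.ndarray     # lateral projected into the z plane, unit

    @classmethod
    def build(cls, lateral_raw, down_raw, forward_raw) -> "_BallFrame":
        fwd = unit(forward_raw)
        lat = unit(lateral_raw)
        down_in_plane = down_raw - np.dot(down_raw, lat) * lat
        down = unit(down_in_plane)
        c_hat = unit(down_raw)
        lat_z = unit(lat - np.dot(lat, c_hat) * c_hat)
        return cls(lateral=lat, down=down, forward=fwd,
                   down_raw=np.asarray(down_raw, dtype=float), lateral_z=lat_z)

    def extract_yz(self, limb: np.ndarray) -> tuple[float, float]:
        """(y, z) projection angles of a proximal limb vector; NaN where
        the projection degenerates."""
        a = float(np.dot(limb, self.lateral))
        b = float(np.dot(limb, self.down))
        g = float(np.dot(limb, self.forward))
        scale = np.linalg.norm(limb)
        y = math.nan
        if math.hypot(a, b) > SINGULARITY_TOL * max(scale, 1.0):
            y = _deg_atan2(-b, a)
        c_hat = unit(self.down_raw)
        z_proj = limb - np.dot(limb, c_hat) * c_hat
        z = math.nan
        if np.linalg.norm(z_proj) > SINGULARITY_TOL * max(scale, 1.0):
            z = _deg_atan2(-float(np.dot(z_proj, self.forward)),
                           float(np.dot(z_proj, self.lateral_z)))
        return y, z

    def apply_yz(self, y_deg: float, z_deg: float) -> np.ndarray:
        """Unit proximal limb direction realizing the (y, z) pair.

        Inverse of :meth:`extract_yz`.  The pair must be hemisphere
        consistent: cos(z) must share its sign with the lateral component
        implied by y (an arm cannot point backwards in the transverse
        plane while pointing forward of the coronal plane).
        """
        y = math.radians(y_deg)
        z = math.radians(z_deg)
        lat, down, fwd = self.lateral, self.down, self.forward
        # decomposition of the raw down reference in the y plane
        p = float(np.dot(unit(self.down_raw), lat))
        q = float(np.dot(unit(self.down_raw), down))
        m = q * math.cos(y) + p * math.sin(y)
        cz = math.cos(z)
        if abs(m) > 1e-12 and abs(cz) > 1e-12 and (m > 0) != (cz > 0):
            raise ValueError(
                f"inconsistent spherical angles y={y_deg:.3f}, z={z_deg:.3f}: "
                "cos(z) must share the sign of the lateral-plane component")
        gamma = 0.0
        if abs(cz) > 1e-12:
            gamma = -m * math.tan(z)
        u = math.cos(y) * lat - math.sin(y) * down + gamma * fwd
        return unit(u)


def _shoulder_frame(vec: AnatomicalVectors, side: str) -> _BallFrame:
    lateral_raw = vec.left_to_right_shoulder if side == "right" \
        else -vec.left_to_right_shoulder
    return _BallFrame.build(lateral_raw, vec.chest_to_pelvis, vec.forward_facing)


def _hip_frame(vec: AnatomicalVectors, side: str) -> _BallFrame:
    lateral_raw = -vec.right_to_left_hip if side == "right" \
        else vec.right_to_left_hip
    return _BallFrame.build(lateral_raw, -vec.global_up, vec.forward_facing_lower)


# ---------------------------------------------------------------------------
# axial rotation read off the distal segment

def twist_references(forward: np.ndarray, proximal_dir: np.ndarray,
                     cross_order: str = "ref_first") -> tuple[np.ndarray, np.ndarray]:
    """In-plane reference pair for the axial (x) rotation.

    Projects the (Backwards-)Forward Facing vector onto the plane normal
    to the proximal limb, and builds the Cross-Elbow / Cross-Knee vector:
    ``cross(reference, -limb)`` for the shoulder, ``cross(-limb,
    reference)`` for the hip (the two constructions are quoted with
    opposite operand order).
    """
    u = unit(proximal_dir)
    ref = project_onto_plane(forward, u)
    nr = np.linalg.norm(ref)
    if nr <= SINGULARITY_TOL:
        raise SingularityError("limb parallel to the forward-facing vector")
    ref = ref / nr
    if cross_order == "ref_first":
        cr = np.cross(ref, -u)
    else:
        cr = np.cross(-u, ref)
    return ref, unit(cr)


def _twist_angle(forward, proximal, distal, cross_order) -> float:
    u = unit(proximal)
    ref, cr = twist_references(forward, u, cross_order)
    x_proj = project_onto_plane(distal, u)
    if np.linalg.norm(x_proj) <= SINGULARITY_TOL * max(np.linalg.norm(distal), 1.0):
        raise SingularityError(
            "distal segment parallel to the proximal limb (straight joint): "
            "axial rotation undefined")
    return _deg_atan2(-float(np.dot(x_proj, cr)), float(np.dot(x_proj, ref)))


# ---------------------------------------------------------------------------
# public per-joint operations (strict: raise on missing/singular)

def _side_ids(side: str, *joints: str) -> list[int]:
    if side not in _SIDES:
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    return [_R[f"{side}_{j}"] for j in joints]


def shoulder_angles(frame: SkeletonFrame, side: str,
                    global_up: np.ndarray = GLOBAL_UP) -> tuple[float, float, float]:
    """(x, y, z) shoulder angles in degrees.

    x is the humeral axial rotation (circumduction), read off the
    forearm's projection; y abduction; z flexion.  Raises
    :class:`MissingJointError` if a required joint is unobserved and
    :class:`SingularityError` at gimbal poses.
    """
    sh, el, wr = _side_ids(side, "shoulder", "elbow", "wrist")
    vec = anatomical_vectors(frame, global_up)
    bf = _shoulder_frame(vec, side)
    s2e = frame.position(el) - frame.position(sh)
    if np.linalg.norm(s2e) <= SINGULARITY_TOL:
        raise SingularityError("shoulder and elbow coincide")
    y, z = bf.extract_yz(s2e)
    if math.isnan(y):
        raise SingularityError("arm parallel to the forward-facing normal: "
                               "y angle undefined")
    if math.isnan(z):
        raise SingularityError("arm parallel to the chest-to-pelvis normal: "
                               "z angle undefined")
    e2w = frame.position(wr) - frame.position(el)
    x = _twist_angle(vec.forward_facing, s2e, e2w, "ref_first")
    return x, y, z


def hip_angles(frame: SkeletonFrame, side: str,
               global_up: np.ndarray = GLOBAL_UP) -> tuple[float, float, float]:
    """(x, y, z) hip angles in degrees; x is read off the shank."""
    hp, kn, an = _side_ids(side, "hip", "knee", "ankle")
    vec = anatomical_vectors(frame, global_up)
    bf = _hip_frame(vec, side)
    h2k = frame.position(kn) - frame.position(hp)
    if np.linalg.norm(h2k) <= SINGULARITY_TOL:
        raise SingularityError("hip and knee coincide")
    y, z = bf.extract_yz(h2k)
    if math.isnan(y):
        raise SingularityError("leg parallel to the forward-facing normal: "
                               "y angle undefined")
    if math.isnan(z):
        raise SingularityError("leg parallel to global up: z angle undefined")
    k2a = frame.position(an) - frame.position(kn)
    # Backwards Facing x Projection: the negated forward vector projected
    # onto the plane normal to the negated hip-to-knee vector
    x = _twist_angle(-vec.forward_facing_lower, h2k, k2a, "limb_first")
    return x, y, z


def elbow_angle(frame: SkeletonFrame, side: str) -> float:
    """Flexion/extension angle between Elbow->Shoulder and Elbow->Wrist;
    180 deg is a straight arm."""
    sh, el, wr = _side_ids(side, "shoulder", "elbow", "wrist")
    from .geometry import angle_between

    return angle_between(frame.position(sh) - frame.position(el),
                         frame.position(wr) - frame.position(el))


def knee_angle(frame: SkeletonFrame, side: str) -> float:
    """Flexion/extension angle between Knee->Hip and Knee->Ankle."""
    hp, kn, an = _side_ids(side, "hip", "knee", "ankle")
    from .geometry import angle_between

    return angle_between(frame.position(hp) - frame.position(kn),
                         frame.position(an) - frame.position(kn))


def spine_angles(frame: SkeletonFrame,
                 global_up: np.ndarray = GLOBAL_UP) -> tuple[float, float]:
    """(x, z) vertebral column angles in degrees.

    x twists the shoulder line against the hip line about Global Up;
    z bends Pelvis-to-Chest away from Global Up in the sagittal plane of
    the hips.  The upright untwisted pose reads (0, 0).
    """
    vec = anatomical_vectors(frame, global_up)
    up = unit(vec.global_up)
    r2l_sh = -vec.left_to_right_shoulder
    sh_proj = project_onto_plane(r2l_sh, up)
    if np.linalg.norm(sh_proj) <= SINGULARITY_TOL:
        raise SingularityError("shoulder line parallel to global up")
    hip_proj = project_onto_plane(vec.right_to_left_hip, up)
    if np.linalg.norm(hip_proj) <= SINGULARITY_TOL:
        raise SingularityError("hip line parallel to global up")
    hp = unit(hip_proj)
    sp = unit(sh_proj)
    x = _deg_atan2(float(np.dot(np.cross(hp, sp), up)), float(np.dot(sp, hp)))
    z_proj = project_onto_plane(vec.pelvis_to_chest, hp)
    if np.linalg.norm(z_proj) <= SINGULARITY_TOL:
        raise SingularityError("torso parallel to the hip line: bend undefined")
    fwd = unit(np.cross(hp, up))  # forward facing from the projected hip line
    z = _deg_atan2(float(np.dot(z_proj, fwd)), float(np.dot(z_proj, up)))
    return x, z


# ---------------------------------------------------------------------------
# whole-frame / whole-sequence extraction (lenient: NaN where undefined)

def extract_frame_angles(frame: SkeletonFrame,
                         global_up: np.ndarray = GLOBAL_UP) -> JointAngleSet:
    """All 18 angle channels for one frame; undefined entries are NaN.

    An angle is undefined when a joint it needs is missing or its
    projection degenerates; each channel fails independently.
    """
    out = {name: math.nan for name in ANGLE_NAMES}

    def attempt(names, fn):
        try:
            vals = fn()
        except (MissingJointError, SingularityError):
            return
        for n, v in zip(names, vals):
            out[n] = v

    for side in _SIDES:
        # y/z need shoulder+elbow only; x additionally needs the wrist,
        # so the triple is attempted in two stages
        def yz(side=side):
            vec = anatomical_vectors(frame, global_up)
            bf = _shoulder_frame(vec, side)
            sh, el = _side_ids(side, "shoulder", "elbow")
            return bf.extract_yz(frame.position(el) - frame.position(sh))

        attempt((f"shoulder_{side}_y", f"shoulder_{side}_z"), yz)

        def sx(side=side):
            vec = anatomical_vectors(frame, global_up)
            sh, el, wr = _side_ids(side, "shoulder", "elbow", "wrist")
            s2e = frame.position(el) - frame.position(sh)
            e2w = frame.position(wr) - frame.position(el)
            return (_twist_angle(vec.forward_facing, s2e, e2w, "ref_first"),)

        attempt((f"shoulder_{side}_x",), sx)

        def hyz(side=side):
            vec = anatomical_vectors(frame, global_up)
            bf = _hip_frame(vec, side)
            hp, kn = _side_ids(side, "hip", "knee")
            return bf.extract_yz(frame.position(kn) - frame.position(hp))

        attempt((f"hip_{side}_y", f"hip_{side}_z"), hyz)

        def hx(side=side):
            vec = anatomical_vectors(frame, global_up)
            hp, kn, an = _side_ids(side, "hip", "knee", "ankle")
            h2k = frame.position(kn) - frame.position(hp)
            k2a = frame.position(an) - frame.position(kn)
            return (_twist_angle(-vec.forward_facing_lower, h2k, k2a,
                                 "limb_first"),)

        attempt((f"hip_{side}_x",), hx)
        attempt((f"elbow_{side}",), lambda side=side: (elbow_angle(frame, side),))
        attempt((f"knee_{side}",), lambda side=side: (knee_angle(frame, side),))

    attempt(("spine_x", "spine_z"), lambda: spine_angles(frame, global_up))

    # NaN values in extract_yz (partial singularities) survive `attempt`;
    # they are already the undefined marker.
    return JointAngleSet.from_vector([out[n] for n in ANGLE_NAMES])


def extract_sequence_angles(sequence: SkeletonSequence,
                            global_up: np.ndarray = GLOBAL_UP) -> AngleSeries:
    """Per-frame angle sets for a whole sequence (NaN = undefined)."""
    sets = [extract_frame_angles(f, global_up) for f in sequence]
    return AngleSeries.from_sets(
        [f.frame_index for f in sequence],
        [f.timestamp for f in sequence],
        sets,
    )
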