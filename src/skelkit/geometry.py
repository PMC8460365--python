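"""Vector primitives for the joint-angle constructions.

All angle extraction reduces to three operations: projecting a vector onto
a plane, the unsigned angle between two vectors, and a betweenness test
that decides the sign of an angle (whether a vector lies inside the convex
cone spanned by two reference vectors in their common plane).
"""

from __future__ import annotations

import numpy as np

#: vectors shorter than this (meters) are treated as degenerate
SINGULARITY_TOL = 1e-8


class SingularityError(ValueError):
    """A projection normal or projected vector vanished; the angle is
    undefined at this pose (gimbal configuration)."""


def _norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v, tol: float = SINGULARITY_TOL) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = _norm(v)
    if n <= tol:
        raise SingularityError("cannot normalize a near-zero vector")
    return v / n


def project_onto_plane(v, normal, tol: float = SINGULARITY_TOL) -> np.ndarray:
    """Component of ``v`` perpendicular to ``normal``.

    The result lies in the plane through the origin with the given normal;
    ``v - result`` is parallel to the normal.
    """
    v = np.asarray(v, dtype=float)
    n = unit(normal, tol)
    return v - np.dot(v, n) * n


def angle_between(u, v, tol: float = SINGULARITY_TOL) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180].

    Computed as atan2(|u x v|, u.v), which keeps full precision near
    collinear pairs where the arccos form loses ~sqrt(eps).
    """
    uu = unit(u, tol)
    vv = unit(v, tol)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(uu, vv)),
                                       np.dot(uu, vv))))


def lies_between(v, a, b, tol_deg: float = 1e-6,
                 coplanar_tol: float = 1e-6) -> bool:
    """True iff ``v`` lies inside the convex cone spanned by ``a`` and ``b``.

    All three vectors must be coplanar (within ``coplanar_tol`` on the unit
    sphere); membership holds when angle(a,v) + angle(v,b) equals
    angle(a,b) within ``tol_deg``.
    """
    va, vb, vv = unit(a), unit(b), unit(v)
    n = np.cross(va, vb)
    if np.linalg.norm(n) > coplanar_tol:
        if abs(np.dot(vv, n / np.linalg.norm(n))) > coplanar_tol:
            raise ValueError("v is not coplanar with a and b")
    return abs(angle_between(a, v) + angle_between(v, b)
               - angle_between(a, b)) <= tol_deg


def signed_angle(v, reference, negative_side, tol: float = SINGULARITY_TOL) -> float:
    """Angle of ``v`` from ``reference``, made negative on one half-plane.

    This realizes the sign rule used throughout the angle constructions:
    the unsigned angle is negated when ``v`` lies between ``negative_side``
    and either ``reference`` or its negation — equivalently, when ``v``
    has a positive component along the part of ``negative_side``
    perpendicular to ``reference``.  All three vectors are expected to be
    coplanar (in the projection plane).
    """
    theta = angle_between(v, reference, tol)
    r = unit(reference, tol)
    side = np.asarray(negative_side, dtype=float)
    side_perp = side - np.dot(side, r) * r
    ns = _norm(side_perp)
    if ns <= tol:
        return theta
    if np.dot(v, side_perp / ns) > 0.0:
        return -theta
    return theta
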