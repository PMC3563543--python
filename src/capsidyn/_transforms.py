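"""Rigid-transform and quaternion helpers.

Quaternions follow the scipy convention (x, y, z, w), scalar last.  A pose is a
pair ``(q, t)``: the world position of a body point ``x`` is ``R(q) @ x + t``.
Composition ``compose(a, b)`` is "a then b expressed in a's frame", i.e. the
pose of B when B's pose relative to A is ``b`` and A's world pose is ``a``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def quat_identity() -> np.ndarray:
    return np.array([0.0, 0.0, 0.0, 1.0])


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product, scalar-last convention: R(q1*q2) = R(q1) @ R(q2)."""
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([-q[0], -q[1], -q[2], q[3]])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion q (scalar-last)."""
    return Rotation.from_quat(q).apply(v)


def quat_from_rotvec(phi: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(phi).as_quat()


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    return Rotation.from_quat(q).as_rotvec()


def pose_compose(qa, ta, qb, tb):
    """Pose of B in world given A's world pose (qa, ta) and B's pose (qb, tb)
    relative to A."""
    q = quat_multiply(qa, qb)
    t = ta + quat_rotate(qa, tb)
    return q, t


def pose_inverse(q, t):
    qi = quat_conjugate(q)
    return qi, -quat_rotate(qi, t)


def pose_relative(qa, ta, qb, tb):
    """Relative pose X of B in A's body frame: pose_b = pose_a o X."""
    qi, ti = pose_inverse(qa, ta)
    return pose_compose(qi, ti, qb, tb)


def rotation_angle(q) -> float:
    """Magnitude of the rotation encoded by q, in radians."""
    return float(np.linalg.norm(Rotation.from_quat(q).as_rotvec()))
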