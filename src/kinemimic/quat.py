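"""Quaternion and rotation helpers.

Conventions used throughout the package: right-handed coordinates, z-up,
meters and radians; quaternions are scalar-first ``[w, x, y, z]``, unit
norm, and canonicalized to a non-negative scalar part where a unique
representative is needed (the double cover maps q and -q to one rotation).
"""

from __future__ import annotations

import numpy as np


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize near-zero quaternion")
    return q / n


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Flip sign so the scalar part is non-negative."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (both scalar-first)."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, dtype=float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, dtype=float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion q."""
    return to_matrix(q) @ np.asarray(v, dtype=float)


def to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def from_matrix(R: np.ndarray) -> np.ndarray:
    # Shepperd's method, numerically safe for all rotation matrices.
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return canonicalize(normalize(q))


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = axis / n
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def from_rotvec(rv: np.ndarray) -> np.ndarray:
    rv = np.asarray(rv, dtype=float)
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        return normalize(np.concatenate([[1.0], 0.5 * rv]))
    return from_axis_angle(rv / angle, angle)


def to_rotvec(q: np.ndarray) -> np.ndarray:
    """Rotation-vector (axis * angle) logarithm, shortest arc."""
    q = canonicalize(normalize(q))
    w = float(np.clip(q[0], -1.0, 1.0))
    vec = q[1:]
    s = float(np.linalg.norm(vec))
    if s < 1e-12:
        return 2.0 * vec  # small-angle limit
    angle = 2.0 * np.arctan2(s, w)
    return (angle / s) * vec


def yaw(q: np.ndarray) -> float:
    """Heading angle: rotation of the body x-axis about the world z-axis."""
    R = to_matrix(q)
    return float(np.arctan2(R[1, 0], R[0, 0]))


def yaw_quat(q: np.ndarray) -> np.ndarray:
    """Yaw-only (heading) part of q, a rotation about world z."""
    return from_axis_angle(np.array([0.0, 0.0, 1.0]), yaw(q))


def geodesic_angle(qa: np.ndarray, qb: np.ndarray) -> float:
    """Angle of the relative rotation between two unit quaternions."""
    return float(np.linalg.norm(to_rotvec(mul(conj(qa), qb))))


def nlerp(qa: np.ndarray, qb: np.ndarray, w: float) -> np.ndarray:
    """Normalized linear interpolation with shortest-arc sign correction."""
    qa = normalize(qa)
    qb = normalize(qb)
    if float(np.dot(qa, qb)) < 0.0:
        qb = -qb
    return normalize((1.0 - w) * qa + w * qb)
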