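"""Unit-quaternion helpers.

Quaternions are stored as ``(w, x, y, z)`` numpy arrays (scalar first).
``rotate(q, v)`` applies the rotation body->world; ``rotate_inv`` maps a
world vector into the body frame.  These are the primitives used both by
the synthetic orientation scripts and by the gradient-descent fusion
filter, so they are kept dependency-free and exactly reproducible.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def multiply(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Hamilton product q ⊗ r."""
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        if angle != 0:
            raise ValueError("zero axis with nonzero angle")
        return IDENTITY.copy()
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def to_axis_angle(q: np.ndarray) -> tuple[np.ndarray, float]:
    q = normalize(q)
    if q[0] < 0:  # keep angle in [0, pi]
        q = -q
    s = np.linalg.norm(q[1:])
    angle = 2.0 * np.arctan2(s, q[0])
    axis = q[1:] / s if s > 1e-15 else np.array([1.0, 0.0, 0.0])
    return axis, angle


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vector v into the world frame: q ⊗ v ⊗ q*."""
    w, r = q[0], q[1:]
    v = np.asarray(v, dtype=float)
    return (w * w - r @ r) * v + 2.0 * (r @ v) * r + 2.0 * w * np.cross(r, v)


def rotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate world-frame vector v into the body frame: q* ⊗ v ⊗ q."""
    w, r = q[0], q[1:]
    v = np.asarray(v, dtype=float)
    return (w * w - r @ r) * v + 2.0 * (r @ v) * r - 2.0 * w * np.cross(r, v)


def slerp(q0: np.ndarray, q1: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation along the shorter arc."""
    q0 = normalize(q0)
    q1 = normalize(q1)
    dot = float(q0 @ q1)
    if dot < 0.0:
        q1, dot = -q1, -dot
    if dot > 1.0 - 1e-12:
        return normalize(q0 + t * (q1 - q0))
    theta = np.arccos(dot)
    s = np.sin(theta)
    return (np.sin((1 - t) * theta) * q0 + np.sin(t * theta) * q1) / s


def angle_between(q0: np.ndarray, q1: np.ndarray) -> float:
    """Geodesic angle (radians) between two orientations."""
    _, angle = to_axis_angle(multiply(conjugate(q0), q1))
    return angle


def integrate_angular_velocity(q: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """One explicit-Euler step of q̇ = ½ q ⊗ (0, ω), renormalized."""
    qdot = 0.5 * multiply(q, np.concatenate([[0.0], omega]))
    return normalize(q + qdot * dt)


def body_angular_velocity(q0: np.ndarray, q1: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity carrying q0 to q1 over dt seconds."""
    dq = multiply(conjugate(q0), q1)
    axis, angle = to_axis_angle(dq)
    return axis * (angle / dt)
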