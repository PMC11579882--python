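"""Scalar-first quaternion helpers on top of scipy's Rotation.

All public wearlab APIs use scalar-first (w, x, y, z) unit quaternions and
the OpenSim-style model frame: x anterior, y up, z to the participant's
right.  The IMU "global" frame is z-up; the fixed -90 deg rotation about x
maps global coordinates into the model frame, (x, y, z) -> (x, z, -y).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

#: gravity in the model frame (y up), m/s^2
MODEL_GRAVITY = np.array([0.0, -9.81, 0.0])

#: fixed rotation global -> model frame: -90 deg about x, (x,y,z) -> (x,z,-y)
GLOBAL_TO_MODEL = Rotation.from_euler("x", -90, degrees=True)
MODEL_TO_GLOBAL = GLOBAL_TO_MODEL.inv()


def as_rotation(q: np.ndarray) -> Rotation:
    """Scalar-first quaternion array (..., 4) -> scipy Rotation."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(q, scalar_first=True)


def from_rotation(rot: Rotation) -> np.ndarray:
    """scipy Rotation -> scalar-first quaternion array."""
    return rot.as_quat(scalar_first=True)


def quat_about_z(angle: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for a rotation of ``angle`` rad about +z."""
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    q = np.zeros(angle.shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., 3] = np.sin(half)
    return q


def twist_about_z(q: np.ndarray) -> np.ndarray:
    """Sagittal (twist-about-z) angle of scalar-first quaternion(s), rad.

    Decomposes q = q_swing * q_twist with the twist axis +z and returns the
    signed twist angle in (-pi, pi].  For a planar rotation about z this is
    exactly the rotation angle.
    """
    q = np.asarray(q, dtype=float)
    w, z = q[..., 0], q[..., 3]
    ang = 2.0 * np.arctan2(z, w)
    # fold into (-pi, pi]
    return np.where(ang > np.pi, ang - 2 * np.pi,
                    np.where(ang <= -np.pi, ang + 2 * np.pi, ang))


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    return from_rotation(as_rotation(q1) * as_rotation(q2))


def quat_inverse(q: np.ndarray) -> np.ndarray:
    return from_rotation(as_rotation(q).inv())


def check_unit(q: np.ndarray, tol: float = 1e-3, what: str = "quaternion") -> np.ndarray:
    """Renormalize quaternions within ``tol`` of unit norm; reject others."""
    q = np.asarray(q, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(
            f"{what} norm off unit by {worst:.3g} (> {tol:g}); refusing to renormalize"
        )
    return q / norms[..., None]


def angular_velocity_body(q: np.ndarray, rate: float) -> np.ndarray:
    """Body-frame angular velocity (rad/s) from a quaternion series.

    Central differences of the relative rotation q_t^-1 q_{t+1}; one-sided
    at the ends.  Rows are scalar-first quaternions sampled at ``rate`` Hz.
    """
    rot = as_rotation(q)
    n = len(q)
    omega = np.zeros((n, 3))
    if n < 2:
        return omega
    # central: 0.5/dt * rotvec( R_{i-1}^-1 R_{i+1} )
    rel = rot[:-2].inv() * rot[2:]
    omega[1:-1] = rel.as_rotvec() * (rate / 2.0)
    omega[0] = (rot[0].inv() * rot[1]).as_rotvec() * rate
    omega[-1] = (rot[-2].inv() * rot[-1]).as_rotvec() * rate
    return omega


def cross_z(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """z-component of r x f for (..., 3) arrays (sagittal moment)."""
    r = np.asarray(r, dtype=float)
    f = np.asarray(f, dtype=float)
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]
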