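"""Small SO(3) toolbox: exponential map, right Jacobian, elementary rotations.

Rotation vectors are in radians. All formulas guard the small-angle limit with
series expansions switched at ``_EPS_ANGLE`` so gradients stay smooth through
the identity.
"""

from __future__ import annotations

import numpy as np

_EPS_ANGLE = 1e-8


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix, hat(v) @ w == v x w."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def exp(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues formula: rotation matrix of a rotation vector."""
    theta = float(np.linalg.norm(rotvec))
    K = hat(rotvec)
    if theta < _EPS_ANGLE:
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * K + b * (K @ K)


def right_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of the exponential map.

    Exp(v + dv) ~= Exp(v) @ Exp(J_r(v) dv); needed to chain-rule gradients
    through rotation-vector increments at finite angle.
    """
    theta = float(np.linalg.norm(rotvec))
    K = hat(rotvec)
    if theta < _EPS_ANGLE:
        return np.eye(3) - 0.5 * K + (K @ K) / 6.0
    a = (1.0 - np.cos(theta)) / theta**2
    b = (theta - np.sin(theta)) / theta**3
    return np.eye(3) - a * K + b * (K @ K)


def rotx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def roty(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def drotx(a: float) -> np.ndarray:
    """d/da of rotx(a)."""
    c, s = np.cos(a), np.sin(a)
    return np.array([[0.0, 0.0, 0.0], [0.0, -s, -c], [0.0, c, -s]])


def droty(a: float) -> np.ndarray:
    """d/da of roty(a)."""
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])
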