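"""Small 3-D geometry helpers used by structure building and mutagenesis."""

from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral_angle", "place_atom", "rotation_about_axis"]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion a-b-c-d in degrees, IUPAC sign convention."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    dihedral: float,
) -> np.ndarray:
    """Place atom D given references A, B, C (NeRF construction).

    D is at distance ``bond`` from C, with angle B-C-D = ``angle`` (degrees)
    and torsion A-B-C-D = ``dihedral`` (degrees).
    """
    ang = np.radians(angle)
    tor = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d2


def rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
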