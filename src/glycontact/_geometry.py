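"""Internal vector-geometry helpers: torsions, angles, internal-coordinate chain building."""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "angle", "place_atom", "rotation_about_axis"]


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float | np.ndarray:
    """Torsion angle a-b-c-d in degrees, IUPAC sign convention, range (-180, 180].

    Looking down b->c, the angle from the plane (a,b,c) to the plane (b,c,d),
    positive clockwise.  Accepts single points of shape (3,) or stacked arrays
    of shape (..., 3); broadcasts over leading axes.
    """
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly onto +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang) if np.ndim(ang) else (
        180.0 if np.isclose(ang, -180.0) else float(ang)
    )


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float | np.ndarray:
    """Angle a-b-c at vertex b, in degrees, range [0, 180]."""
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out if np.ndim(out) else float(out)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom D given three predecessors A, B, C (NeRF construction).

    D is at ``bond_length`` from C, with angle B-C-D of ``bond_angle_deg`` and
    torsion A-B-C-D of ``torsion_deg`` (same sign convention as :func:`dihedral`).
    """
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    # local displacement in the frame where C is origin, BC along -x
    d_local = np.array([
        -bond_length * np.cos(theta),
        bond_length * np.sin(theta) * np.cos(chi),
        -bond_length * np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` (need not be unit) by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
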