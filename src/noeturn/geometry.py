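"""Small vector-geometry kernel: angles, dihedrals, NeRF placement, axis rotations.

All positions are (..., 3) float64 arrays. Units are whatever the caller uses
consistently (the package uses nm internally, Angstrom only at PDB boundaries).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "angle",
    "dihedral",
    "place_atom",
    "rotation_matrix",
    "rotate_about_axis",
    "wrap_deg",
]


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC convention (-180, 180]."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(-np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, theta: float, tau: float) -> np.ndarray:
    """Place atom X bonded to ``c`` using NeRF.

    ``bond`` is the c-X distance, ``theta`` the b-c-X angle (degrees) and
    ``tau`` the torsion a-b-c-X (degrees).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(theta)
    ta = np.radians(tau)
    # local displacement in the frame where bc is +x
    d = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(ta),
            bond * np.sin(th) * np.sin(ta),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:  # colinear reference; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` (normalised internally)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def rotate_about_axis(coords: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate ``coords`` rigidly about the line through ``origin`` along ``axis``."""
    R = rotation_matrix(axis, angle_deg)
    origin = np.asarray(origin, float)
    return (coords - origin) @ R.T + origin


def wrap_deg(x):
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)
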