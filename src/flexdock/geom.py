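"""Small geometry helpers: dihedrals, axis rotations, internal-coordinate placement."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    # map -180 -> 180 to keep the half-open convention
    w = np.where(w == -180.0, 180.0, w)
    if np.isscalar(angle) or getattr(angle, "ndim", 1) == 0:
        return float(w)
    return w


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    # sign flipped so the result follows the IUPAC convention
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


def rotate_about_axis(coords: np.ndarray, point_a, point_b, angle_deg: float) -> np.ndarray:
    """Rotate `coords` (n,3) by angle_deg about the axis from point_a to point_b."""
    a = np.asarray(point_a, dtype=float)
    axis = np.asarray(point_b, dtype=float) - a
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate rotation axis")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / n)
    return rot.apply(np.asarray(coords, dtype=float) - a) + a


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given positions of A, B, C so that |CD| = bond,
    angle(B,C,D) = angle_deg and dihedral(A,B,C,D) = dihedral_deg (NeRF)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a unit quaternion (x, y, z, w)."""
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation quaternion via the subgroup algorithm."""
    u1, u2, u3 = rng.random(3)
    s1, s2 = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    return np.array([s1 * np.sin(t2), s1 * np.cos(t2), s2 * np.sin(t3), s2 * np.cos(t3)])
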