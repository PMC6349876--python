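"""Coordinate geometry primitives: dihedrals, internal-coordinate atom
placement (NeRF), and Kabsch superposition RMSD.

All lengths are in nm and all angles in degrees unless noted otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "kabsch_rmsd",
    "kabsch_rotation",
    "random_rotation",
]


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Looking down the p1->p2 axis, a clockwise rotation of the far bond
    relative to the near bond is positive; result lies in (-180, 180].
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(-y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond_length, angle(b,c,d) = bond_angle
    and dihedral(a,b,c,d) = torsion (natural extension reference frame)."""
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch_rotation(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning `moving` onto `fixed`.

    Returns (R, centroid_moving, centroid_fixed) such that
    (moving - cm) @ R.T + cf best fits fixed in the least-squares sense.
    """
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, cm, cf


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD between two point sets over rigid rotation + translation.

    Symmetric in its arguments and invariant under proper rigid transforms
    of either argument.  Requires equal-length sets of >= 3 points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    r, cm, cf = kabsch_rotation(a, b)
    fitted = (a - cm) @ r.T + cf
    return float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
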