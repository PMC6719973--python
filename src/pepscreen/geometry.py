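"""Low-level 3-D geometry primitives shared by the builders and scorers.

All angles are in degrees, all lengths in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "angle",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "superpose",
    "rmsd",
    "frame_from_coords",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = normalize(np.asarray(a, float) - b)
    w = normalize(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def vector_angle(u: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors, degrees."""
    cu = normalize(np.asarray(u, float))
    cw = normalize(np.asarray(w, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(cu, cw), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, normalize(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond_length, angle(b,c,d) =
    bond_angle and dihedral(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    phi = np.radians(torsion)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    u = normalize(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def superpose(mobile: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch superposition; returns (R, t) such that mobile @ R.T + t ~= fixed."""
    mobile = np.asarray(mobile, float)
    fixed = np.asarray(fixed, float)
    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (mobile - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, fc - rot @ mc


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def frame_from_coords(coords: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame that is equivariant under rigid-body
    transforms of ``coords`` (used to orient surface sample points so that
    numeric areas are rotation invariant)."""
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        return np.eye(3)
    origin = coords[0]
    e1 = None
    for p in coords[1:]:
        v = p - origin
        if np.linalg.norm(v) > 1e-6:
            e1 = v / np.linalg.norm(v)
            break
    if e1 is None:
        return np.eye(3)
    for p in coords[1:]:
        v = p - origin
        w = v - np.dot(v, e1) * e1
        if np.linalg.norm(w) > 1e-6:
            e2 = w / np.linalg.norm(w)
            return np.stack([e1, e2, np.cross(e1, e2)])
    return np.eye(3)
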