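"""Low-level 3D geometry helpers.

Internal-coordinate (z-matrix style) atom placement, rigid-body
superposition and frame utilities shared by the builder and the analysis
layers.  All lengths are in Angstrom, all angles in degrees at the public
surface (radians internally where noted).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom D given three reference atoms using internal coordinates.

    D is at distance ``bond`` from ``c``, with angle B-C-D equal to
    ``angle_deg`` and dihedral A-B-C-D equal to ``dihedral_deg`` (NeRF
    construction).
    """
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        # colinear reference atoms: pick an arbitrary perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        -bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``target`` (Kabsch via
    :func:`scipy.spatial.transform.Rotation.align_vectors`).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    moved = (mobile - cm) @ R.T + ct
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    t = ct - cm @ R.T
    return R, t, rmsd


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (for invariance tests)."""
    return Rotation.random(random_state=rng).as_matrix()


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]
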