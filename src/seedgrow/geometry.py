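"""Small rigid-body geometry kernel: superposition, internal-coordinate placement."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of `mobile` onto `reference` (both (n,3), n>=3
    non-collinear preferred; n=3 works).

    Returns (R, t) such that mobile @ R.T + t approximates reference.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    R = rot.as_matrix()
    t = cr - R @ cm
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, the c-d bond length, the b-c-d angle and
    the a-b-c-d dihedral (natural extension reference frame)."""
    angle = np.radians(angle_deg)
    tor = -np.radians(dihedral_deg)  # frame below is left-handed w.r.t. IUPAC sign
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(tor),
        bond * np.sin(angle) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about an axis through `origin`."""
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return (coords - origin) @ rot.as_matrix().T + origin
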