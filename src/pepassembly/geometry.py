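"""Vector geometry primitives: angles, torsions, NeRF atom placement.

These are the building blocks shared by the chain builder and the turn
criteria.  All coordinates are in Å, all angles in degrees, torsions in
(-180, 180] with the IUPAC sign convention (looking B→C, clockwise rotation
of D relative to A is positive).
"""

from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral", "place_atom", "random_rotation", "wrap_angle"]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(deg) else wrapped


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle A-B-C in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle A-B-C-D in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C by internal coordinates.

    D is at distance ``bond_length`` from C, with bond angle B-C-D equal to
    ``angle_deg`` and torsion A-B-C-D equal to ``torsion_deg`` (the NeRF
    construction used throughout structure building).
    """
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            -np.sin(theta) * np.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed 3x3 rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
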