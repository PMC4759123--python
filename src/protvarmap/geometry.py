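"""Internal-coordinate geometry: dihedrals and NeRF atom placement.

The natural-extension reference frame (NeRF) construction places atom D
given the positions of three reference atoms A, B, C, the bond length
C-D, the bond angle B-C-D and the torsion A-B-C-D.  It is the standard
way to convert internal coordinates (Z-matrix entries, backbone phi/psi,
side-chain chi angles) into Cartesian coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "dihedral", "bond_angle", "GeometryError"]


class GeometryError(ValueError):
    """Degenerate reference geometry (collinear frame atoms)."""


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b0, b1, b2 = b - a, c - b, d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(-np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle: float, torsion: float
               ) -> np.ndarray:
    """Place atom D from reference atoms A, B, C (NeRF).

    ``bond`` is the C-D distance in Angstrom, ``angle`` the B-C-D bond
    angle in degrees, ``torsion`` the A-B-C-D dihedral in degrees.  The
    construction is exact: re-measuring the three internal coordinates of
    the returned point recovers the inputs.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-8 or nn < 1e-8:
        raise GeometryError("collinear or coincident reference atoms")
    bc_hat = bc / nbc
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    th = np.radians(angle)
    ph = np.radians(torsion)
    d_local = bond * np.array([
        -np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)
    ])
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local
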