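"""Coordinate mathematics: signed torsions, point reflection, internal-coordinate placement.

All angles are in degrees, all distances in Angstrom.  The torsion sign
convention is the IUPAC one: looking from the second atom toward the third,
a clockwise rotation of the far bond relative to the near bond is positive.
Torsions are reported in the half-open range (-180, +180], with the exact
boundary mapped to +180 so that an ideal trans peptide bond has a single
representable value.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "dihedral_angle",
    "signed_improper",
    "point_reflect",
    "place_atom",
    "angle_between",
    "wrap_angle",
]

#: cross-product norm (A^2) below which three points count as collinear
COLLINEARITY_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when a torsion or frame is requested for collinear/coincident points."""


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle into (-180, +180], mapping the boundary to +180."""
    a = math.fmod(angle_deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion of p1 about the p2->p3 axis relative to p4, in degrees.

    Returns a value in (-180, +180].  0 means p1 and p4 are eclipsed (cis);
    +180 means they are anti (trans).  Raises
    :class:`DegenerateGeometryError` when p2 == p3 or either atom triple is
    collinear, rather than silently returning 0.
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise DegenerateGeometryError("axis atoms p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEARITY_TOL:
        raise DegenerateGeometryError("p1, p2, p3 are collinear")
    if np.linalg.norm(n2) < COLLINEARITY_TOL:
        raise DegenerateGeometryError("p2, p3, p4 are collinear")
    m = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def signed_improper(quadruple) -> float:
    """Signed improper angle over an ordered atom quadruple.

    This is simply :func:`dihedral_angle` applied to four atoms that do not
    form a linear bonded chain.  With the substituent orderings used by the
    chirality templates, the sign of the improper discriminates enantiomers.
    """
    q = list(quadruple)
    if len(q) != 4:
        raise ValueError("improper needs exactly four points")
    return dihedral_angle(*q)


def point_reflect(p, center) -> np.ndarray:
    """Reflect point ``p`` through ``center``: returns ``2*center - p``."""
    return 2.0 * _as_vec(center) - _as_vec(p)


def angle_between(a, b, c) -> float:
    """Bond angle a-b-c in degrees (vertex at b)."""
    u = _as_vec(a) - _as_vec(b)
    v = _as_vec(c) - _as_vec(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident points in angle")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` from internal coordinates.

    The returned point satisfies ``|d - c| == bond_length``,
    ``angle(b, c, d) == bond_angle`` and
    ``dihedral_angle(a, b, c, d) == torsion`` (each to ~1e-6).

    This is the standard natural-extension reference-frame construction used
    by sequential polymer builders.
    """
    a, b, c = _as_vec(a), _as_vec(b), _as_vec(c)
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise ValueError("bond_angle must lie strictly between 0 and 180 degrees")
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < 1e-12:
        raise DegenerateGeometryError("frame atoms b and c coincide")
    bc = bc / nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < COLLINEARITY_TOL:
        raise DegenerateGeometryError("frame atoms a, b, c are collinear")
    n = n / nn
    m = np.cross(n, bc)
    theta = math.radians(bond_angle)
    tau = math.radians(torsion)
    # minus sign on the out-of-plane term keeps the torsion sign consistent
    # with dihedral_angle's convention
    d = (
        c
        - bond_length * math.cos(theta) * bc
        + bond_length * math.sin(theta) * (math.cos(tau) * m - math.sin(tau) * n)
    )
    return d
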