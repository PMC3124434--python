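"""Ideal peptide geometry shared by the fixture builder and the regularizer.

Bond lengths and angles follow standard small-molecule-derived peptide
geometry (Engh/Huber-style values, rounded).  They are used both to
construct synthetic peptides from internal coordinates and as the reference
values of the harmonic bonded terms in local regularization.
"""

from __future__ import annotations

__all__ = [
    "BACKBONE_BONDS",
    "SIDECHAIN_BONDS",
    "IDEAL_ANGLES",
    "ideal_bond_length",
    "ideal_angle",
    "residue_bonds",
    "THREE_LETTER",
]

THREE_LETTER = {
    "A": "ALA", "G": "GLY", "Q": "GLN", "T": "THR", "I": "ILE", "P": "PRO",
}

# intra-residue backbone bonds (atom pairs) with ideal lengths in Angstrom
BACKBONE_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("N", "H"): 1.010,
    ("CA", "HA"): 1.090,
    ("CA", "HA2"): 1.090,
    ("CA", "HA3"): 1.090,
}

#: inter-residue peptide bond C(n)-N(n+1)
PEPTIDE_CN = 1.329

SIDECHAIN_BONDS = {
    "ALA": {("CA", "CB"): 1.530},
    "GLY": {},
    "GLN": {
        ("CA", "CB"): 1.530,
        ("CB", "CG"): 1.520,
        ("CG", "CD"): 1.516,
        ("CD", "OE1"): 1.231,
        ("CD", "NE2"): 1.328,
    },
    "THR": {
        ("CA", "CB"): 1.540,
        ("CB", "OG1"): 1.433,
        ("CB", "CG2"): 1.521,
    },
    "ILE": {
        ("CA", "CB"): 1.540,
        ("CB", "CG1"): 1.530,
        ("CB", "CG2"): 1.521,
        ("CG1", "CD1"): 1.513,
    },
    "PRO": {
        ("CA", "CB"): 1.530,
        ("CB", "CG"): 1.492,
        ("CG", "CD"): 1.503,
        ("CD", "N"): 1.473,
    },
    "ACE": {("CH3", "C"): 1.510, ("C", "O"): 1.231},
    "NH2": {},
}

# bond-angle reference values in degrees, keyed by the (a, b, c) atom-name
# triple with the vertex at b; looked up symmetrically
IDEAL_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.2,
    ("O", "C", "N"): 123.0,
    ("C", "N", "CA"): 121.7,
    ("C", "N", "H"): 119.15,
    ("H", "N", "CA"): 119.15,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
    ("N", "CA", "HA"): 108.5,
    ("C", "CA", "HA"): 108.5,
    ("CB", "CA", "HA"): 107.946,
    ("CA", "CB", "CG"): 114.1,
    ("CB", "CG", "CD"): 112.6,
    ("CG", "CD", "OE1"): 120.8,
    ("CG", "CD", "NE2"): 116.5,
    ("OE1", "CD", "NE2"): 122.7,
    ("CA", "CB", "OG1"): 109.6,
    ("CA", "CB", "CG2"): 110.5,
    ("OG1", "CB", "CG2"): 108.888,
    ("CA", "CB", "CG1"): 110.4,
    ("CG1", "CB", "CG2"): 108.475,
    ("CB", "CG1", "CD1"): 113.8,
    ("N", "CA", "HA2"): 109.5,
    ("N", "CA", "HA3"): 109.5,
    ("C", "CA", "HA2"): 109.5,
    ("C", "CA", "HA3"): 109.5,
    ("HA2", "CA", "HA3"): 107.566,
}

_DEFAULT_ANGLE = 109.5


def ideal_bond_length(res_name: str, a: str, b: str) -> float:
    """Ideal length for the (a, b) bond within a residue, in Angstrom."""
    for table in (SIDECHAIN_BONDS.get(res_name, {}), BACKBONE_BONDS):
        if (a, b) in table:
            return table[(a, b)]
        if (b, a) in table:
            return table[(b, a)]
    raise KeyError(f"no ideal length for {res_name} {a}-{b}")


def ideal_angle(a: str, b: str, c: str) -> float:
    """Ideal a-b-c angle in degrees, falling back to tetrahedral."""
    return IDEAL_ANGLES.get((a, b, c), IDEAL_ANGLES.get((c, b, a), _DEFAULT_ANGLE))


def residue_bonds(res_name: str) -> list:
    """All intra-residue bonds (atom-name pairs) defined for a residue."""
    bonds = []
    if res_name in ("ACE", "NH2"):
        bonds.extend(SIDECHAIN_BONDS.get(res_name, {}))
        return bonds
    for pair in BACKBONE_BONDS:
        bonds.append(pair)
    bonds.extend(SIDECHAIN_BONDS.get(res_name, {}))
    return bonds
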