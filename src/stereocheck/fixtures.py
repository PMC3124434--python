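"""Synthetic structures with known stereochemistry, built from internal coordinates.

The builder constructs peptides atom by atom with the natural-extension
reference frame, using ideal bond lengths and angles and user-chosen
phi/psi/omega dihedrals.  Stereochemical perturbations are injectable at
build time: individual peptide bonds can be made cis (omega = 0), and
individual residues can be inverted to the D-configuration at C-alpha by
swapping the side-chain and alpha-hydrogen placements about the N-CA-C
plane, which flips the chirality without distorting the backbone.

The default build spec is the 15-residue alanine/glutamine alpha-helix
AAQAAAAQAAAAQAA at helical phi/psi; the standard perturbation sites used
throughout the tests are the Gln8 C-alpha and the Gln8-Ala9 peptide bond.

These structures are a test bed, not physical models: there are no
nonbonded interactions, rotamers are canonical, and the proline ring is not
exactly closed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from ._ideal import PEPTIDE_CN, THREE_LETTER, ideal_angle, ideal_bond_length
from .geometry import place_atom
from .structure_io import Atom, Residue, Structure, write_structure

__all__ = [
    "BuildSpec",
    "build_peptide",
    "mirror_structure",
    "write_fixture_set",
    "nucleotide_fixture",
    "FIXTURE_FILES",
]

def _direction_from_angles(u1, u2, ang1: float, ang2: float, positive_side: bool):
    """Unit direction making the given angles (degrees) with unit vectors
    u1 and u2; ``positive_side`` picks which side of the (u1, u2) plane."""
    c = float(np.dot(u1, u2))
    a1, a2 = np.cos(np.radians(ang1)), np.cos(np.radians(ang2))
    denom = 1.0 - c * c
    alpha = (a1 - c * a2) / denom
    beta = (a2 - c * a1) / denom
    gamma_sq = 1.0 - (alpha * alpha + beta * beta + 2.0 * alpha * beta * c)
    gamma = np.sqrt(max(gamma_sq, 0.0))
    if not positive_side:
        gamma = -gamma
    p = np.cross(u1, u2)
    p = p / np.linalg.norm(p)
    return alpha * u1 + beta * u2 + gamma * p


def _per_residue(value, n: int, name: str) -> list:
    if np.isscalar(value):
        return [float(value)] * n
    vals = [float(v) for v in value]
    if len(vals) != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return vals


@dataclass
class BuildSpec:
    """Recipe for a synthetic peptide.

    ``cis_bonds`` holds 1-based bond indices (bond i links residues i and
    i+1) whose omega is set to 0; ``d_residues`` holds 1-based residue
    indices inverted to D at C-alpha.
    """

    sequence: str = "AAQAAAAQAAAAQAA"
    phi: Union[float, Sequence[float]] = -57.0
    psi: Union[float, Sequence[float]] = -47.0
    omega: Union[float, Sequence[float]] = 180.0
    cis_bonds: tuple = ()
    d_residues: tuple = ()
    include_hydrogens: bool = True
    capped: bool = False
    chain_id: str = "A"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise ValueError("sequence must be non-empty")
        for letter in self.sequence:
            if letter not in THREE_LETTER:
                raise ValueError(
                    f"unsupported residue letter {letter!r}; "
                    f"supported: {''.join(sorted(THREE_LETTER))}"
                )
        bad = [i for i in self.cis_bonds if not 1 <= i <= n - 1]
        if bad:
            raise ValueError(f"cis_bonds indices out of range [1, {n - 1}]: {bad}")
        bad = [i for i in self.d_residues if not 1 <= i <= n]
        if bad:
            raise ValueError(f"d_residues indices out of range [1, {n}]: {bad}")


def _tetrahedral_pair(n_pos, ca_pos, c_pos, d_config: bool, glycine: bool = False):
    """Directions for the CB and HA substituents of a C-alpha.

    Each direction is solved from its two ideal bond angles to N and C;
    which side of the N-CA-C plane carries the side chain decides L vs D.
    The side assignment is calibrated so the default (L) configuration
    gives a positive improper over the (N, CA, C, CB) quadruple.
    Returns (cb_dir, ha_dir) unit vectors.
    """
    u1 = n_pos - ca_pos
    u1 = u1 / np.linalg.norm(u1)
    u2 = c_pos - ca_pos
    u2 = u2 / np.linalg.norm(u2)
    side = -1.0 if d_config else 1.0
    if glycine:
        cb_angles = (ideal_angle("N", "CA", "HA2"), ideal_angle("C", "CA", "HA2"))
        ha_angles = (ideal_angle("N", "CA", "HA3"), ideal_angle("C", "CA", "HA3"))
    else:
        cb_angles = (ideal_angle("N", "CA", "CB"), ideal_angle("C", "CA", "CB"))
        ha_angles = (ideal_angle("N", "CA", "HA"), ideal_angle("C", "CA", "HA"))
    cb = _direction_from_angles(u1, u2, *cb_angles, side > 0)
    ha = _direction_from_angles(u1, u2, *ha_angles, side < 0)
    return cb, ha


def _build_side_chain(res: Residue, letter: str, positions: dict, d_config: bool,
                      include_hydrogens: bool) -> None:
    """Place CB/HA and the side chain beyond CB from canonical rotamers."""
    name3 = THREE_LETTER[letter]
    n, ca, c = positions["N"], positions["CA"], positions["C"]
    cb_dir, ha_dir = _tetrahedral_pair(n, ca, c, d_config, glycine=(letter == "G"))

    def add(atom_name: str, pos, element: Optional[str] = None) -> None:
        el = element if element is not None else atom_name.strip("0123456789'")[0]
        res.atoms.append(Atom(serial=0, name=atom_name, element=el, alt_loc="",
                              position=pos))
        positions[atom_name] = np.asarray(pos, dtype=float)

    if letter == "G":
        if include_hydrogens:
            add("HA2", ca + 1.090 * cb_dir, "H")
            add("HA3", ca + 1.090 * ha_dir, "H")
        return

    cb = ca + ideal_bond_length(name3, "CA", "CB") * cb_dir
    add("CB", cb, "C")
    if include_hydrogens:
        add("HA", ca + 1.090 * ha_dir, "H")

    def branch(frame: tuple, atom_name: str, length_pair: tuple, angle: tuple,
               torsion: float) -> None:
        a, b, cpos = (positions[x] for x in frame)
        pos = place_atom(a, b, cpos, ideal_bond_length(name3, *length_pair),
                         ideal_angle(*angle), torsion)
        add(atom_name, pos)

    if letter == "Q":
        branch(("N", "CA", "CB"), "CG", ("CB", "CG"), ("CA", "CB", "CG"), 180.0)
        branch(("CA", "CB", "CG"), "CD", ("CG", "CD"), ("CB", "CG", "CD"), 180.0)
        branch(("CB", "CG", "CD"), "OE1", ("CD", "OE1"), ("CG", "CD", "OE1"), 0.0)
        branch(("CB", "CG", "CD"), "NE2", ("CD", "NE2"), ("CG", "CD", "NE2"), 180.0)
    elif letter == "T":
        # torsion offsets calibrated so the natural (3R) configuration gives
        # a positive improper over (CA, CB, OG1, CG2)
        branch(("N", "CA", "CB"), "OG1", ("CB", "OG1"), ("CA", "CB", "OG1"), -60.0)
        branch(("N", "CA", "CB"), "CG2", ("CB", "CG2"), ("CA", "CB", "CG2"), 60.0)
    elif letter == "I":
        # natural (3S): CG1 and CG2 orderings calibrated like THR
        branch(("N", "CA", "CB"), "CG1", ("CB", "CG1"), ("CA", "CB", "CG1"), -60.0)
        branch(("N", "CA", "CB"), "CG2", ("CB", "CG2"), ("CA", "CB", "CG2"), 60.0)
        branch(("CA", "CB", "CG1"), "CD1", ("CG1", "CD1"), ("CB", "CG1", "CD1"), 180.0)
    elif letter == "P":
        branch(("N", "CA", "CB"), "CG", ("CB", "CG"), ("CA", "CB", "CG"), 30.0)
        branch(("CA", "CB", "CG"), "CD", ("CG", "CD"), ("CB", "CG", "CD"), -35.0)


def build_peptide(spec: Optional[BuildSpec] = None) -> Structure:
    """Build a peptide from a :class:`BuildSpec` via sequential placement.

    Guarantees (verified by the round-trip tests): every built backbone
    dihedral matches the spec within 1 degree, and every chiral center's
    improper is positive unless the residue is listed in ``d_residues``.
    """
    spec = spec or BuildSpec()
    n_res = len(spec.sequence)
    phi = _per_residue(spec.phi, n_res, "phi")
    psi = _per_residue(spec.psi, n_res, "psi")
    omega = _per_residue(spec.omega, max(n_res - 1, 1), "omega")
    for i in spec.cis_bonds:
        omega[i - 1] = 0.0

    s = Structure(source_path="<built>")
    chain: list = []
    s.chains[spec.chain_id] = chain

    # backbone trace in placement order: N, CA, C per residue
    bb: list = []  # (n_pos, ca_pos, c_pos)
    for i in range(n_res):
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = np.array([ideal_bond_length("ALA", "N", "CA"), 0.0, 0.0])
            ang = np.radians(ideal_angle("N", "CA", "C"))
            c_pos = ca_pos + ideal_bond_length("ALA", "CA", "C") * np.array(
                [-np.cos(ang), np.sin(ang), 0.0]
            )
        else:
            pn, pca, pc = bb[i - 1]
            n_pos = place_atom(pn, pca, pc, PEPTIDE_CN,
                               ideal_angle("CA", "C", "N"), psi[i - 1])
            ca_pos = place_atom(pca, pc, n_pos, ideal_bond_length("ALA", "N", "CA"),
                                ideal_angle("C", "N", "CA"), omega[i - 1])
            c_pos = place_atom(pc, n_pos, ca_pos, ideal_bond_length("ALA", "CA", "C"),
                               ideal_angle("N", "CA", "C"), phi[i])
        bb.append((n_pos, ca_pos, c_pos))

    for i, letter in enumerate(spec.sequence):
        name3 = THREE_LETTER[letter]
        res = Residue(name=name3, chain_id=spec.chain_id, seq_num=i + 1,
                      insertion_code="")
        chain.append(res)
        n_pos, ca_pos, c_pos = bb[i]
        positions = {"N": n_pos, "CA": ca_pos, "C": c_pos}
        res.atoms.append(Atom(0, "N", "N", "", n_pos))
        res.atoms.append(Atom(0, "CA", "C", "", ca_pos))
        res.atoms.append(Atom(0, "C", "C", "", c_pos))
        # carbonyl O anti to the next N about the CA->C axis, so that
        # omega' = omega - 180 holds exactly on built structures
        o_pos = place_atom(n_pos, ca_pos, c_pos, ideal_bond_length(name3, "C", "O"),
                           ideal_angle("CA", "C", "O"), psi[i] + 180.0)
        res.atoms.append(Atom(0, "O", "O", "", o_pos))
        positions["O"] = o_pos
        if spec.include_hydrogens and i > 0 and letter != "P":
            pn, pca, pc = bb[i - 1]
            h_pos = place_atom(pca, pc, n_pos, ideal_bond_length(name3, "N", "H"),
                               ideal_angle("C", "N", "H"), omega[i - 1] + 180.0)
            res.atoms.append(Atom(0, "H", "H", "", h_pos))
            positions["H"] = h_pos
        _build_side_chain(res, letter, positions, d_config=(i + 1) in spec.d_residues,
                          include_hydrogens=spec.include_hydrogens)
        # keep canonical PDB ordering: heavy atoms first, then hydrogens
        res.atoms.sort(key=lambda a: a.is_hydrogen)

    if spec.capped:
        _add_caps(s, spec, bb)
    _assign_serials(s)
    return s


def _add_caps(s: Structure, spec: BuildSpec, bb: list) -> None:
    """Acetyl (ACE) and amide (NH2) capping groups at the termini."""
    chain = s.chains[spec.chain_id]
    n1, ca1, c1 = bb[0]
    c_ace = place_atom(c1, ca1, n1, PEPTIDE_CN, ideal_angle("C", "N", "CA"), 180.0)
    o_ace = place_atom(ca1, n1, c_ace, 1.231, ideal_angle("CA", "C", "O"), 0.0)
    ch3 = place_atom(ca1, n1, c_ace, 1.510, ideal_angle("CA", "C", "N"), 180.0)
    ace = Residue(name="ACE", chain_id=spec.chain_id, seq_num=0, insertion_code="")
    ace.atoms = [Atom(0, "CH3", "C", "", ch3), Atom(0, "C", "C", "", c_ace),
                 Atom(0, "O", "O", "", o_ace)]
    chain.insert(0, ace)
    nn, nca, nc = bb[-1]
    psi_last = _per_residue(spec.psi, len(spec.sequence), "psi")[-1]
    n_cap = place_atom(nn, nca, nc, PEPTIDE_CN, ideal_angle("CA", "C", "N"), psi_last)
    nh2 = Residue(name="NH2", chain_id=spec.chain_id,
                  seq_num=len(spec.sequence) + 1, insertion_code="")
    nh2.atoms = [Atom(0, "N", "N", "", n_cap)]
    chain.append(nh2)


def _assign_serials(s: Structure) -> None:
    for i, atom in enumerate(s.atoms(), start=1):
        atom.serial = i


def mirror_structure(s: Structure) -> Structure:
    """Mirror image: every z coordinate negated, topology untouched."""
    m = copy.deepcopy(s)
    for atom in m.atoms():
        atom.position = atom.position * np.array([1.0, 1.0, -1.0])
    return m


def _expdta(method: str) -> str:
    return f"EXPDTA    {method}"


def _cispep(ser: int, r1: str, c1: str, s1: int, r2: str, c2: str, s2: int,
            angle: float) -> str:
    return (
        f"CISPEP {ser:3d} {r1:>3s} {c1:1s} {s1:4d}    {r2:>3s} {c2:1s} {s2:4d}"
        f"       {0:3d}       {angle:6.2f}"
    )


#: file names of the standard battery, in emission order
FIXTURE_FILES = (
    "clean.pdb",
    "one_cis.pdb",
    "one_d.pdb",
    "combined.pdb",
    "chain_break.pdb",
    "missing_atom.pdb",
    "cispep_matched.pdb",
    "cispep_false.pdb",
)


def write_fixture_set(directory) -> list:
    """Emit the standard fixture battery plus an expected-outcome TSV.

    The battery covers: a clean helix; single-cis, single-D and combined
    variants (perturbation sites: bond 8-9 and residue 8); a chain break; a
    missing carbonyl oxygen; and two header-validation twins with a correct
    and a false CISPEP record.  Expected detection/cross-validation counts
    are computed from the build recipes at generation time and written
    beside the files as ``expected_counts.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seq = "AAQAAAAQAAAAQAA"
    cispep_hdr = _cispep(1, "GLN", "A", 8, "ALA", "A", 9, 0.0)

    def make(name, spec, method, headers=(), mutate=None):
        s = build_peptide(spec)
        if mutate is not None:
            mutate(s)
        text = write_structure(s, header_lines=[_expdta(method), *headers])
        path = directory / name
        path.write_text(text)
        return path

    def break_chain(s: Structure) -> None:
        res = s.get_residue(("A", 8, ""))
        for atom in res.atoms:
            atom.position = atom.position + np.array([50.0, 0.0, 0.0])

    def drop_oxygen(s: Structure) -> None:
        res = s.get_residue(("A", 8, ""))
        res.atoms = [a for a in res.atoms if a.name != "O"]

    paths = [
        make("clean.pdb", BuildSpec(seq), "X-RAY DIFFRACTION"),
        make("one_cis.pdb", BuildSpec(seq, cis_bonds=(8,)), "X-RAY DIFFRACTION"),
        make("one_d.pdb", BuildSpec(seq, d_residues=(8,)), "SOLUTION NMR"),
        make("combined.pdb", BuildSpec(seq, cis_bonds=(8,), d_residues=(8,)),
             "ELECTRON MICROSCOPY"),
        make("chain_break.pdb", BuildSpec(seq), "X-RAY DIFFRACTION",
             mutate=break_chain),
        make("missing_atom.pdb", BuildSpec(seq), "X-RAY DIFFRACTION",
             mutate=drop_oxygen),
        make("cispep_matched.pdb", BuildSpec(seq, cis_bonds=(8,)),
             "X-RAY DIFFRACTION", headers=[cispep_hdr]),
        make("cispep_false.pdb", BuildSpec(seq), "X-RAY DIFFRACTION",
             headers=[cispep_hdr]),
    ]

    # expectations derived from the build recipes, not from re-detection
    rows = [
        "file\tcis_count\tchirality_error_count\tunevaluable_bonds"
        "\tunevaluable_centers\tunreported_cis\theader_only_cis",
        "clean.pdb\t0\t0\t0\t0\t0\t0",
        "one_cis.pdb\t1\t0\t0\t0\t1\t0",
        "one_d.pdb\t0\t1\t0\t0\t0\t0",
        "combined.pdb\t1\t1\t0\t0\t1\t0",
        "chain_break.pdb\t0\t0\t0\t0\t0\t0",
        "missing_atom.pdb\t0\t0\t1\t0\t0\t0",
        "cispep_matched.pdb\t1\t0\t0\t0\t0\t0",
        "cispep_false.pdb\t0\t0\t0\t0\t0\t1",
    ]
    (directory / "expected_counts.tsv").write_text("\n".join(rows) + "\n")
    return paths


# Idealized nucleoside coordinates (synthetic, generated once from an
# embedded CIP-correct small-molecule model and rounded to 0.001 A).  Only
# the atoms needed by the sugar chirality templates are included.
_ADENOSINE_ATOMS = (
    ("O5'", (-2.324, -2.226, 1.368)),
    ("C5'", (-2.607, -1.269, 0.352)),
    ("C4'", (-2.409, 0.145, 0.904)),
    ("O4'", (-1.045, 0.276, 1.380)),
    ("C1'", (-0.373, 1.241, 0.542)),
    ("N9", (0.986, 0.804, 0.302)),
    ("C8", (2.111, 1.536, 0.586)),
    ("N7", (3.214, 0.887, 0.276)),
    ("C5", (2.779, -0.314, -0.246)),
    ("C6", (3.467, -1.429, -0.754)),
    ("N6", (4.852, -1.499, -0.829)),
    ("N1", (2.749, -2.495, -1.173)),
    ("C2", (1.402, -2.424, -1.110)),
    ("N3", (0.635, -1.409, -0.661)),
    ("C4", (1.395, -0.386, -0.234)),
    ("C2'", (-1.219, 1.417, -0.719)),
    ("O2'", (-1.077, 2.707, -1.312)),
    ("C3'", (-2.619, 1.221, -0.157)),
    ("O3'", (-3.016, 2.467, 0.446)),
)


def nucleotide_fixture(kind: str = "RNA") -> str:
    """PDB text for one synthetic idealized nucleotide residue.

    ``kind`` is ``"RNA"`` (adenosine, residue name A) or ``"DNA"``
    (2'-deoxyadenosine, residue name DA; the O2' atom is absent).  The
    coordinates are a synthetic stand-in with correct natural sugar
    stereochemistry, intended for template tests only.
    """
    if kind not in ("RNA", "DNA"):
        raise ValueError("kind must be 'RNA' or 'DNA'")
    res_name = "A" if kind == "RNA" else "DA"
    res = Residue(name=res_name, chain_id="A", seq_num=1, insertion_code="")
    for name, xyz in _ADENOSINE_ATOMS:
        if kind == "DNA" and name == "O2'":
            continue
        element = name.strip("0123456789'")[0]
        res.atoms.append(Atom(0, name, element, "", np.array(xyz)))
    s = Structure()
    s.chains["A"] = [res]
    _assign_serials(s)
    return write_structure(s)
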