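"""Correction moves and local restrained regularization.

Correcting a stereochemical anomaly is a two-step, user-driven operation:

1. a *reflection move* relocates a single peripheral atom to the target
   side — the carbonyl oxygen is reflected through its carbon, or an amide
   or alpha hydrogen through its nitrogen or chiral carbon.  C-alpha atoms
   are never moved, to minimize the structural impact;
2. a *local regularization* relaxes the residues around the site under a
   harmonic bonded-term model (bonds, angles, peptide planarity impropers)
   plus a target-state dihedral restraint, completing the isomerization or
   inversion while leaving everything outside the cutoff untouched.

The regularizer is an internal bonded-term minimizer rather than a link to
an external MD engine: the contract is the same (local, restrained
relaxation), the runtime dependency is gone.  Harmonic dihedral restraints
use k*(delta)^2 with periodic wrapping of delta into (-180, 180].

The module also generates preventive restraints that preserve the current
isomerization state of every peptide bond and chiral center, serialized to
the extra-bonds text dialect (one ``dihedral``/``improper`` line with four
0-based atom indices, a force constant in kcal/mol/rad^2, and a reference
angle in degrees) consumable by NAMD's extraBonds facility.  Such restraint
files are meant for relaxation stages only and should be removed before
production equilibrium runs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from ._ideal import PEPTIDE_CN, SIDECHAIN_BONDS, ideal_angle, ideal_bond_length, residue_bonds
from .geometry import point_reflect, signed_improper, wrap_angle
from .stereo_detect import (
    DEFAULT_TEMPLATES,
    ChiralCenterRecord,
    DetectionReport,
    PeptideBondRecord,
)
from .structure_io import ResidueId, Structure

__all__ = [
    "RestraintSpec",
    "RegularizationResult",
    "MissingAtomError",
    "flip_peptide_bond",
    "flip_chirality",
    "regularize_local",
    "correct_peptide_bond",
    "correct_chirality",
    "generate_restraints",
    "write_extrabonds",
    "parse_extrabonds",
    "omega_restraint",
    "improper_restraint",
]

# force constants of the internal bonded model (kcal/mol per A^2 or rad^2)
BOND_K = 300.0
ANGLE_K = 80.0
PLANARITY_K = 40.0
DEFAULT_RESTRAINT_K = 200.0
DEFAULT_CUTOFF = 8.0
DEFAULT_MAX_ITERATIONS = 2000
DEFAULT_GRADIENT_TOL = 0.1  # kcal/mol/A


class MissingAtomError(KeyError):
    """A correction move needs an atom the structure does not contain."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class RestraintSpec:
    """One harmonic dihedral/improper restraint on four atoms.

    ``atom_indices`` are 0-based positions in the structure's serialized
    atom order (the order :func:`stereocheck.structure_io.write_structure`
    emits).  ``force_constant`` is in kcal/mol/rad^2 and
    ``reference_angle`` in degrees.
    """

    kind: str  # "dihedral" | "improper"
    atom_indices: tuple
    force_constant: float = DEFAULT_RESTRAINT_K
    reference_angle: float = 180.0

    def __post_init__(self) -> None:
        if self.kind not in ("dihedral", "improper"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        idx = tuple(int(i) for i in self.atom_indices)
        if len(idx) != 4 or len(set(idx)) != 4 or min(idx) < 0:
            raise ValueError(f"need four distinct non-negative indices, got {idx}")
        object.__setattr__(self, "atom_indices", idx)


@dataclass
class RegularizationResult:
    structure: Structure
    converged: bool
    n_iterations: int
    max_gradient: float
    mobile_residues: list = field(default_factory=list)


def _require_atom(res, name: str, context: str):
    atom = res.atom(name)
    if atom is None:
        raise MissingAtomError(
            f"atom {name!r} not present in {res.name} {res.rid}: {context}"
        )
    return atom


def flip_peptide_bond(s: Structure, bond: PeptideBondRecord, move: str) -> Structure:
    """Reflect the chosen peptide-group atom to the other isomer's side.

    ``move`` is ``"O"`` (carbonyl oxygen of residue i, reflected through its
    carbon) or ``"H"`` (amide hydrogen of residue j, reflected through its
    nitrogen).  Hydrogen moves are unavailable when the model has no
    hydrogens (typical of X-ray structures) and for Xaa-Pro bonds, which
    have no amide hydrogen; the oxygen move is always the fallback.
    Returns a modified copy; the input is untouched.
    """
    move = move.upper()
    if move == "CA":
        raise ValueError("C-alpha atoms are not allowed to move")
    if move not in ("O", "H"):
        raise ValueError(f"move must be 'O' or 'H', got {move!r}")
    out = copy.deepcopy(s)
    res_i = out.get_residue(bond.residue_i)
    res_j = out.get_residue(bond.residue_j)
    if res_i is None or res_j is None:
        raise KeyError(f"bond residues {bond.residue_i}/{bond.residue_j} not in structure")
    if move == "O":
        target = _require_atom(res_i, "O", "cannot reflect the carbonyl oxygen")
        center = _require_atom(res_i, "C", "cannot reflect O without its carbon")
    else:
        target = _require_atom(
            res_j, "H",
            "no amide hydrogen (hydrogen-free model or Xaa-Pro bond); move O instead",
        )
        center = _require_atom(res_j, "N", "cannot reflect H without its nitrogen")
    target.position = point_reflect(target.position, center.position)
    return out


#: hydrogen atom name(s) attached to each supported chiral center
_CENTER_HYDROGENS = {
    "CA": ("HA",),
    "CB": ("HB",),
    "C1'": ("H1'",),
    "C2'": ("H2'",),
    "C3'": ("H3'",),
    "C4'": ("H4'",),
}


def flip_chirality(s: Structure, center: ChiralCenterRecord) -> Structure:
    """Reflect the chiral center's hydrogen through the center atom.

    The hydrogen is the smallest substituent, so moving it perturbs the
    structure least; the subsequent :func:`regularize_local` under a
    mirrored improper restraint completes the inversion of the heavy-atom
    arrangement.  Raises :class:`MissingAtomError` when the hydrogen is
    absent (add hydrogens first).
    """
    out = copy.deepcopy(s)
    res = out.get_residue(center.residue)
    if res is None:
        raise KeyError(f"residue {center.residue} not in structure")
    center_atom = _require_atom(res, center.center, "chiral center atom missing")
    h_names = _CENTER_HYDROGENS.get(center.center, ())
    h_atom = next((res.atom(n) for n in h_names if res.atom(n) is not None), None)
    if h_atom is None:
        raise MissingAtomError(
            f"no hydrogen ({'/'.join(h_names) or '?'}) on chiral center "
            f"{center.center} of {res.name} {res.rid}; add hydrogens first"
        )
    h_atom.position = point_reflect(h_atom.position, center_atom.position)
    return out


# ---------------------------------------------------------------------------
# bonded-term model


# planarity impropers of the peptide group; reference values measured on an
# ideal planar peptide (they hold for both isomers, so these terms enforce
# planarity without biasing cis against trans)
_PLANARITY_O = ("CA_i", "N_j", "C_i", "O_i")
_PLANARITY_H = ("CA_j", "C_i", "N_j", "H_j")


class _BondedModel:
    """Vectorized harmonic bonded-term energy over one structure."""

    def __init__(self, s: Structure, restraints: Sequence[RestraintSpec] = ()):
        atoms = list(s.atoms())
        owners = [res for res in s.residues() for _ in res.atoms]
        self.n_atoms = len(atoms)
        self.x0 = np.array([a.position for a in atoms], dtype=float)
        index = s.atom_index_map()

        bonds: list = []      # (i, j, r0)
        adjacency: dict = {}  # atom index -> set of bonded atom indices

        def add_bond(i: int, j: int, r0: float) -> None:
            bonds.append((i, j, r0))
            adjacency.setdefault(i, set()).add(j)
            adjacency.setdefault(j, set()).add(i)

        known = set(SIDECHAIN_BONDS)
        for res in s.residues():
            if res.name not in known:
                continue  # no bonded template: atoms carry no internal terms
            for a, b in residue_bonds(res.name):
                ia = index.get((res.rid, a))
                ib = index.get((res.rid, b))
                if ia is not None and ib is not None:
                    add_bond(ia, ib, ideal_bond_length(res.name, a, b))

        impropers: list = []  # (i, j, k, l, ref_deg, k_force)
        for chain in s.chains.values():
            for res_i, res_j in zip(chain, chain[1:]):
                ci = index.get((res_i.rid, "C"))
                nj = index.get((res_j.rid, "N"))
                if ci is None or nj is None:
                    continue
                if np.linalg.norm(self.x0[ci] - self.x0[nj]) > 2.0:
                    continue
                add_bond(ci, nj, PEPTIDE_CN)
                cai = index.get((res_i.rid, "CA"))
                oi = index.get((res_i.rid, "O"))
                caj = index.get((res_j.rid, "CA"))
                hj = index.get((res_j.rid, "H"))
                if None not in (cai, oi):
                    impropers.append((cai, nj, ci, oi, 180.0, PLANARITY_K))
                if None not in (caj, hj):
                    impropers.append((caj, ci, nj, hj, 180.0, PLANARITY_K))

        names = [a.name for a in atoms]
        angles: list = []  # (i, j, k, theta0_deg)
        for j, neighbors in adjacency.items():
            nb = sorted(neighbors)
            for ai in range(len(nb)):
                for ak in range(ai + 1, len(nb)):
                    i, k = nb[ai], nb[ak]
                    angles.append((i, j, k, ideal_angle(names[i], names[j], names[k])))

        for r in restraints:
            if max(r.atom_indices) >= self.n_atoms:
                raise IndexError(f"restraint indices {r.atom_indices} out of range")
            i, j, k, l = r.atom_indices
            impropers.append((i, j, k, l, r.reference_angle, r.force_constant))

        self.owners = owners
        self._bond_idx = np.array([(b[0], b[1]) for b in bonds], dtype=int).reshape(-1, 2)
        self._bond_r0 = np.array([b[2] for b in bonds], dtype=float)
        self._angle_idx = np.array([(a[0], a[1], a[2]) for a in angles], dtype=int).reshape(-1, 3)
        self._angle_t0 = np.radians([a[3] for a in angles])
        self._dih_idx = np.array([(d[0], d[1], d[2], d[3]) for d in impropers],
                                 dtype=int).reshape(-1, 4)
        self._dih_ref = np.radians([d[4] for d in impropers])
        self._dih_k = np.array([d[5] for d in impropers], dtype=float)

    def energy_grad(self, coords: np.ndarray):
        x = coords.reshape(self.n_atoms, 3)
        energy = 0.0
        grad = np.zeros_like(x)

        if len(self._bond_idx):
            i, j = self._bond_idx[:, 0], self._bond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self._bond_r0
            energy += BOND_K * float(np.sum(dr * dr))
            g = (2.0 * BOND_K * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(grad, i, g)
            np.add.at(grad, j, -g)

        if len(self._angle_idx):
            i, j, k = (self._angle_idx[:, c] for c in range(3))
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
            nv = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.maximum(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
            dt = theta - self._angle_t0
            energy += ANGLE_K * float(np.sum(dt * dt))
            pref = 2.0 * ANGLE_K * dt
            gi = (pref / (nu * sin_t))[:, None] * (cos_t[:, None] * uh - vh)
            gk = (pref / (nv * sin_t))[:, None] * (cos_t[:, None] * vh - uh)
            np.add.at(grad, i, gi)
            np.add.at(grad, k, gk)
            np.add.at(grad, j, -(gi + gk))

        if len(self._dih_idx):
            i, j, k, l = (self._dih_idx[:, c] for c in range(4))
            b1 = x[j] - x[i]
            b2 = x[k] - x[j]
            b3 = x[l] - x[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.maximum(np.linalg.norm(b2, axis=1), 1e-12)
            n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
            n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
            m = np.cross(n1, b2 / nb2[:, None])
            phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))
            dphi = phi - self._dih_ref
            dphi = np.arctan2(np.sin(dphi), np.cos(dphi))  # wrap into (-pi, pi]
            energy += float(np.sum(self._dih_k * dphi * dphi))
            pref = 2.0 * self._dih_k * dphi
            gi = (nb2 / n1sq)[:, None] * n1
            gl = (-nb2 / n2sq)[:, None] * n2
            s12 = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
            s32 = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
            gj = -(1.0 + s12) * gi + s32 * gl
            gk = -(1.0 + s32) * gl + s12 * gi
            np.add.at(grad, i, pref[:, None] * gi)
            np.add.at(grad, j, pref[:, None] * gj)
            np.add.at(grad, k, pref[:, None] * gk)
            np.add.at(grad, l, pref[:, None] * gl)

        return energy, grad


def _as_rid_list(site) -> list:
    if isinstance(site, tuple) and len(site) == 3 and not isinstance(site[0], tuple):
        return [site]
    return [tuple(r) for r in site]


def regularize_local(
    s: Structure,
    site: Union[ResidueId, Iterable],
    cutoff: float = DEFAULT_CUTOFF,
    targets: Sequence[RestraintSpec] = (),
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    gradient_tol: float = DEFAULT_GRADIENT_TOL,
) -> RegularizationResult:
    """Locally minimize the bonded-term model around ``site``.

    Mobile atoms are those of residues having any atom within ``cutoff``
    (Angstrom) of any atom of the site residue(s); every other atom is
    bit-identical in the output.  ``targets`` are additional harmonic
    dihedral restraints (typically the target isomer or configuration).
    On non-convergence within the iteration budget the best coordinates
    found are returned with ``converged=False`` and a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    site_rids = _as_rid_list(site)
    site_residues = [s.get_residue(r) for r in site_rids]
    if any(r is None for r in site_residues):
        missing = [r for r, res in zip(site_rids, site_residues) if res is None]
        raise KeyError(f"site residue(s) not in structure: {missing}")

    out = copy.deepcopy(s)
    model = _BondedModel(out, restraints=targets)

    site_xyz = np.array(
        [a.position for res in site_residues for a in res.atoms], dtype=float
    )
    mobile = np.zeros(model.n_atoms, dtype=bool)
    mobile_rids: list = []
    pos = 0
    atoms_per_res = [(res, len(res.atoms)) for res in out.residues()]
    for res, n in atoms_per_res:
        block = model.x0[pos:pos + n]
        dmin = np.min(np.linalg.norm(block[:, None, :] - site_xyz[None, :, :], axis=2))
        if dmin <= cutoff:
            mobile[pos:pos + n] = True
            mobile_rids.append(res.rid)
        pos += n

    x_full = model.x0.copy()
    mob_idx = np.where(mobile)[0]

    def fun(xm):
        x_full[mob_idx] = xm.reshape(-1, 3)
        e, g = model.energy_grad(x_full.ravel())
        return e, g[mob_idx].ravel()

    res_opt = _scipy_minimize(
        fun,
        x_full[mob_idx].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "maxfun": 10 * max_iterations,
                 "ftol": 1e-12, "gtol": 1e-3 * gradient_tol},
    )
    x_full[mob_idx] = res_opt.x.reshape(-1, 3)
    _, g = model.energy_grad(x_full.ravel())
    max_grad = float(np.max(np.abs(g[mob_idx]))) if len(mob_idx) else 0.0
    converged = max_grad <= gradient_tol
    if not converged:
        warnings.warn(
            f"regularization did not converge (max gradient {max_grad:.3g} "
            f"kcal/mol/A after {res_opt.nit} iterations); returning best found",
            stacklevel=2,
        )
    # write back only the mobile atoms so frozen ones stay bit-identical
    flat_atoms = list(out.atoms())
    for idx in mob_idx:
        flat_atoms[idx].position = x_full[idx].copy()
    return RegularizationResult(
        structure=out,
        converged=converged,
        n_iterations=int(res_opt.nit),
        max_gradient=max_grad,
        mobile_residues=mobile_rids,
    )


# ---------------------------------------------------------------------------
# restraint construction


_OMEGA_ATOMS = (("i", "CA"), ("i", "C"), ("j", "N"), ("j", "CA"))


def omega_restraint(s: Structure, bond: PeptideBondRecord, reference_angle: float,
                    force_constant: float = DEFAULT_RESTRAINT_K) -> RestraintSpec:
    """Dihedral restraint on the omega atoms CA(i), C(i), N(j), CA(j)."""
    index = s.atom_index_map()
    rids = {"i": bond.residue_i, "j": bond.residue_j}
    try:
        idx = tuple(index[(rids[which], name)] for which, name in _OMEGA_ATOMS)
    except KeyError as exc:
        raise MissingAtomError(f"omega atom missing for bond restraint: {exc}") from exc
    return RestraintSpec("dihedral", idx, force_constant, reference_angle)


def _template_for(residue_name: str, center: str):
    for tpl in DEFAULT_TEMPLATES:
        if residue_name in tpl.residues and tpl.center == center:
            return tpl
    raise KeyError(f"no chirality template for {residue_name} {center}")


def improper_restraint(s: Structure, center: ChiralCenterRecord, reference_angle: float,
                       force_constant: float = DEFAULT_RESTRAINT_K) -> RestraintSpec:
    """Improper restraint over the center's template quadruple."""
    tpl = _template_for(center.residue_name, center.center)
    index = s.atom_index_map()
    try:
        idx = tuple(index[(center.residue, name)] for name in tpl.quadruple())
    except KeyError as exc:
        raise MissingAtomError(f"template atom missing for improper restraint: {exc}") from exc
    return RestraintSpec("improper", idx, force_constant, reference_angle)


def generate_restraints(s: Structure, report: DetectionReport,
                        force_constant: float = DEFAULT_RESTRAINT_K) -> list:
    """Harmonic restraints preserving the current stereochemistry.

    One omega dihedral restraint per evaluable peptide bond (reference 180
    for trans bonds, 0 for cis bonds the user chose to keep) and one
    improper restraint per evaluable chiral center (reference = its current
    improper).  Indices refer to the structure's serialized atom order.
    """
    specs: list = []
    for bond in report.peptide_bonds:
        if not bond.evaluable:
            continue
        ref = 0.0 if bond.is_cis else 180.0
        specs.append(omega_restraint(s, bond, ref, force_constant))
    for center in report.chiral_centers:
        if not center.evaluable:
            continue
        specs.append(improper_restraint(s, center, center.improper, force_constant))
    return specs


def write_extrabonds(restraints: Sequence[RestraintSpec]) -> str:
    """Serialize restraints to extra-bonds text, one line per restraint."""
    lines = []
    for r in restraints:
        i, j, k, l = r.atom_indices
        lines.append(f"{r.kind} {i} {j} {k} {l} {r.force_constant!r} {r.reference_angle!r}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_extrabonds(text: str) -> list:
    """Inverse of :func:`write_extrabonds` (lossless round trip)."""
    out: list = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed extra-bonds line: {line!r}")
        kind, *rest = parts
        out.append(RestraintSpec(kind, tuple(int(p) for p in rest[:4]),
                                 float(rest[4]), float(rest[5])))
    return out


# ---------------------------------------------------------------------------
# convenience drivers (flip + regularize in one call)


def correct_peptide_bond(s: Structure, bond: PeptideBondRecord, move: str = "O",
                         cutoff: float = DEFAULT_CUTOFF,
                         force_constant: float = DEFAULT_RESTRAINT_K,
                         target: str = "trans",
                         **regularize_kwargs) -> RegularizationResult:
    """Flip one peptide-group atom, then regularize toward the target isomer."""
    if target not in ("trans", "cis"):
        raise ValueError("target must be 'trans' or 'cis'")
    flipped = flip_peptide_bond(s, bond, move)
    ref = 180.0 if target == "trans" else 0.0
    restraint = omega_restraint(flipped, bond, ref, force_constant)
    return regularize_local(flipped, [bond.residue_i, bond.residue_j],
                            cutoff=cutoff, targets=[restraint], **regularize_kwargs)


def correct_chirality(s: Structure, center: ChiralCenterRecord,
                      cutoff: float = DEFAULT_CUTOFF,
                      force_constant: float = DEFAULT_RESTRAINT_K,
                      **regularize_kwargs) -> RegularizationResult:
    """Flip the center's hydrogen, then regularize toward the mirrored improper."""
    res = s.get_residue(center.residue)
    if res is None:
        raise KeyError(f"residue {center.residue} not in structure")
    tpl = _template_for(center.residue_name, center.center)
    current = signed_improper([res.atom(n).position for n in tpl.quadruple()])
    flipped = flip_chirality(s, center)
    restraint = improper_restraint(flipped, center, wrap_angle(-current), force_constant)
    return regularize_local(flipped, center.residue, cutoff=cutoff,
                            targets=[restraint], **regularize_kwargs)
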