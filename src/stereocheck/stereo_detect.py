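"""Detection of cis peptide bonds and chirality anomalies.

Peptide bonds are classified through the dihedral omega-prime over
O(n), C(n), N(n+1), CA(n+1) — equivalent to the conventional omega over
CA(n), C(n), N(n+1), CA(n+1) but built from atom names that are unique
within the two residues.  Omega-prime is ~0 deg for a trans bond and ~180
for cis, so a bond is flagged cis when |omega'| exceeds the threshold
(default 85 deg, strict inequality).  The threshold is applied to the
magnitude: the sign of a torsion depends only on the viewing convention and
carries no cis/trans information.

Chiral centers are tested through a signed improper dihedral over
non-hydrogen substituents with the chiral atom inside the quadruple.  The
substituent orderings in :data:`DEFAULT_TEMPLATES` are calibrated so that
every naturally occurring configuration (L-amino acids, beta-D-sugars)
yields a positive improper; a negative improper therefore flags an unusual
configuration.  With the quadruple order (s1, center, s2, s3) the improper
sign equals the sign of the triple product
det[s1 - c, s2 - c, s3 - c], which is the CIP-style orientation test used
as an independent oracle in the test suite.

Note that a flagged center is not necessarily an error: D-amino acids occur
in biology (bacterial cell walls, non-ribosomal peptides), and pre-proline
cis bonds are usually genuine.  Detection and correction are deliberately
separate, user-driven steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np

from .geometry import DegenerateGeometryError, dihedral_angle, signed_improper
from .structure_io import (
    DNA_RESIDUES,
    RNA_RESIDUES,
    STANDARD_AMINO_ACIDS,
    Residue,
    ResidueId,
    Structure,
)

__all__ = [
    "DetectionConfig",
    "PeptideBondRecord",
    "ChiralTemplate",
    "ChiralCenterRecord",
    "DetectionReport",
    "DEFAULT_TEMPLATES",
    "enumerate_peptide_bonds",
    "classify_peptide_bond",
    "enumerate_chiral_centers",
    "evaluate_chiral_center",
    "check_structure",
]


@dataclass
class DetectionConfig:
    """Tunable detection parameters.

    omega_prime_threshold: |omega'| above which a peptide bond counts as cis
        (degrees, strict inequality).
    peptide_bond_max_cn_distance: C(n)-N(n+1) distance cutoff establishing
        that two consecutive residues are actually bonded (Angstrom); pairs
        farther apart are chain breaks, not peptide bonds.
    """

    omega_prime_threshold: float = 85.0
    peptide_bond_max_cn_distance: float = 2.0
    check_proteins: bool = True
    check_nucleic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.omega_prime_threshold < 180.0:
            raise ValueError("omega_prime_threshold must lie in (0, 180)")


@dataclass
class PeptideBondRecord:
    residue_i: ResidueId
    residue_j: ResidueId
    residue_i_name: str = ""
    residue_j_name: str = ""
    omega: Optional[float] = None
    omega_prime: Optional[float] = None
    is_cis: bool = False
    pre_proline: bool = False
    evaluable: bool = True
    reason_unevaluable: str = ""


@dataclass(frozen=True)
class ChiralTemplate:
    """One chiral-center definition: residues it applies to, the center atom,
    and the ordered non-hydrogen substituent triple.  The improper is
    measured over the quadruple (s1, center, s2, s3); orderings are
    calibrated so the naturally occurring configuration gives
    ``expected_sign`` (+1)."""

    residues: frozenset
    center: str
    substituents: tuple  # (s1, s2, s3)
    expected_sign: int = 1

    def quadruple(self) -> tuple:
        s1, s2, s3 = self.substituents
        return (s1, self.center, s2, s3)


_PURINES = frozenset({"A", "G", "I", "DA", "DG", "DI"})
_PYRIMIDINES = frozenset({"C", "U", "DC", "DT"})
_NUCLEOTIDES = DNA_RESIDUES | RNA_RESIDUES

DEFAULT_TEMPLATES: tuple = (
    # C-alpha of every standard amino acid except glycine; L gives + improper
    ChiralTemplate(STANDARD_AMINO_ACIDS - {"GLY"}, "CA", ("N", "C", "CB")),
    # second centers at C-beta
    ChiralTemplate(frozenset({"THR"}), "CB", ("CA", "OG1", "CG2")),
    ChiralTemplate(frozenset({"ILE"}), "CB", ("CA", "CG1", "CG2")),
    # sugar centers; beta-D-ribo/deoxyribofuranose gives + improper
    ChiralTemplate(_PURINES, "C1'", ("O4'", "C2'", "N9")),
    ChiralTemplate(_PYRIMIDINES, "C1'", ("O4'", "C2'", "N1")),
    ChiralTemplate(RNA_RESIDUES, "C2'", ("C3'", "C1'", "O2'")),
    ChiralTemplate(_NUCLEOTIDES, "C3'", ("C4'", "C2'", "O3'")),
    ChiralTemplate(_NUCLEOTIDES, "C4'", ("C5'", "C3'", "O4'")),
)


@dataclass
class ChiralCenterRecord:
    residue: ResidueId
    residue_name: str
    center: str
    improper: Optional[float] = None
    flagged: bool = False
    evaluable: bool = True
    reason_unevaluable: str = ""


@dataclass
class DetectionReport:
    peptide_bonds: list = field(default_factory=list)
    chiral_centers: list = field(default_factory=list)
    residues_checked: int = 0
    residues_total: int = 0

    @property
    def cis_count(self) -> int:
        return sum(1 for b in self.peptide_bonds if b.is_cis)

    @property
    def chirality_error_count(self) -> int:
        return sum(1 for c in self.chiral_centers if c.flagged)

    @property
    def unevaluable_bond_count(self) -> int:
        return sum(1 for b in self.peptide_bonds if not b.evaluable)

    @property
    def unevaluable_center_count(self) -> int:
        return sum(1 for c in self.chiral_centers if not c.evaluable)

    @property
    def anomaly_count(self) -> int:
        return self.cis_count + self.chirality_error_count

    def cis_bonds(self) -> list:
        return [b for b in self.peptide_bonds if b.is_cis]

    def flagged_centers(self) -> list:
        return [c for c in self.chiral_centers if c.flagged]

    def to_tsv(self) -> str:
        rows = ["kind\tsite\tnames\tangle_deg\tflag\tpre_proline\tevaluable\treason"]
        for b in self.peptide_bonds:
            site = f"{_rid_str(b.residue_i)}-{_rid_str(b.residue_j)}"
            ang = "" if b.omega_prime is None else f"{b.omega_prime:.2f}"
            rows.append(
                f"peptide_bond\t{site}\t{b.residue_i_name}-{b.residue_j_name}\t{ang}"
                f"\t{'cis' if b.is_cis else 'trans'}\t{int(b.pre_proline)}"
                f"\t{int(b.evaluable)}\t{b.reason_unevaluable}"
            )
        for c in self.chiral_centers:
            ang = "" if c.improper is None else f"{c.improper:.2f}"
            rows.append(
                f"chiral_center\t{_rid_str(c.residue)}:{c.center}\t{c.residue_name}\t{ang}"
                f"\t{'flagged' if c.flagged else 'ok'}\t0\t{int(c.evaluable)}"
                f"\t{c.reason_unevaluable}"
            )
        return "\n".join(rows) + "\n"

    def to_json(self) -> str:
        payload = {
            "residues_checked": self.residues_checked,
            "residues_total": self.residues_total,
            "cis_count": self.cis_count,
            "chirality_error_count": self.chirality_error_count,
            "unevaluable_bond_count": self.unevaluable_bond_count,
            "unevaluable_center_count": self.unevaluable_center_count,
            "peptide_bonds": [asdict(b) for b in self.peptide_bonds],
            "chiral_centers": [asdict(c) for c in self.chiral_centers],
        }
        return json.dumps(payload, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _rid_str(rid: ResidueId) -> str:
    chain, seq, icode = rid
    return f"{chain}:{seq}{icode}"


@dataclass
class _BondCandidate:
    residue_i: Residue
    residue_j: Residue
    evaluable: bool = True
    reason: str = ""


_BOND_ATOMS_I = ("CA", "C", "O")
_BOND_ATOMS_J = ("N", "CA")


def _checkable_protein(res: Residue, cfg: DetectionConfig) -> bool:
    # HETATM entries are only checked when they carry a standard residue
    # name: cofactor/ligand chirality is out of scope.
    return cfg.check_proteins and res.is_standard_amino_acid


def enumerate_peptide_bonds(s: Structure, cfg: Optional[DetectionConfig] = None) -> list:
    """Candidate peptide bonds: consecutive protein residues in a chain whose
    C(n)-N(n+1) distance is within the cutoff.

    Pairs farther apart than the cutoff (chain breaks) yield no candidate at
    all; candidates missing any of the five required heavy atoms are
    returned marked unevaluable, naming the missing atom.
    """
    cfg = cfg or DetectionConfig()
    out: list = []
    if not cfg.check_proteins:
        return out
    for residues in s.chains.values():
        for res_i, res_j in zip(residues, residues[1:]):
            if not (_checkable_protein(res_i, cfg) and _checkable_protein(res_j, cfg)):
                continue
            c = res_i.atom("C")
            n = res_j.atom("N")
            if c is not None and n is not None:
                if np.linalg.norm(c.position - n.position) > cfg.peptide_bond_max_cn_distance:
                    continue  # chain break, not a bond
            missing = [a for a in _BOND_ATOMS_I if a not in res_i]
            missing += [a for a in _BOND_ATOMS_J if a not in res_j]
            if missing:
                out.append(
                    _BondCandidate(res_i, res_j, evaluable=False,
                                   reason="missing " + ", ".join(missing))
                )
            else:
                out.append(_BondCandidate(res_i, res_j))
    return out


def classify_peptide_bond(candidate: _BondCandidate,
                          cfg: Optional[DetectionConfig] = None) -> PeptideBondRecord:
    """Measure omega and omega-prime on one candidate and classify it."""
    cfg = cfg or DetectionConfig()
    res_i, res_j = candidate.residue_i, candidate.residue_j
    rec = PeptideBondRecord(
        residue_i=res_i.rid,
        residue_j=res_j.rid,
        residue_i_name=res_i.name,
        residue_j_name=res_j.name,
        pre_proline=(res_j.name == "PRO"),
    )
    if not candidate.evaluable:
        rec.evaluable = False
        rec.reason_unevaluable = candidate.reason
        return rec
    try:
        pos = lambda res, name: res.atom(name).position  # noqa: E731
        rec.omega = dihedral_angle(pos(res_i, "CA"), pos(res_i, "C"),
                                   pos(res_j, "N"), pos(res_j, "CA"))
        rec.omega_prime = dihedral_angle(pos(res_i, "O"), pos(res_i, "C"),
                                         pos(res_j, "N"), pos(res_j, "CA"))
    except DegenerateGeometryError as exc:
        rec.evaluable = False
        rec.reason_unevaluable = f"degenerate geometry: {exc}"
        return rec
    rec.is_cis = abs(rec.omega_prime) > cfg.omega_prime_threshold
    return rec


@dataclass
class _CenterCandidate:
    residue: Residue
    template: ChiralTemplate
    evaluable: bool = True
    reason: str = ""


def enumerate_chiral_centers(s: Structure,
                             templates: Iterable = DEFAULT_TEMPLATES,
                             cfg: Optional[DetectionConfig] = None) -> list:
    """Candidate chiral centers per the template table.

    Standard amino acids (except glycine) contribute CA; Thr and Ile
    additionally CB; nucleotides contribute C1'/C3'/C4', plus C2' for
    ribonucleotides.  Candidates with template atoms missing are marked
    unevaluable.
    """
    cfg = cfg or DetectionConfig()
    out: list = []
    for res in s.residues():
        if res.is_standard_amino_acid and not cfg.check_proteins:
            continue
        if res.is_nucleotide and not cfg.check_nucleic:
            continue
        for tpl in templates:
            if res.name not in tpl.residues:
                continue
            missing = [a for a in (tpl.center, *tpl.substituents) if a not in res]
            if missing:
                out.append(_CenterCandidate(res, tpl, evaluable=False,
                                            reason="missing " + ", ".join(missing)))
            else:
                out.append(_CenterCandidate(res, tpl))
    return out


def evaluate_chiral_center(candidate: _CenterCandidate) -> ChiralCenterRecord:
    """Measure the signed improper of one candidate center and flag it when
    the sign disagrees with the naturally occurring configuration."""
    res, tpl = candidate.residue, candidate.template
    rec = ChiralCenterRecord(residue=res.rid, residue_name=res.name, center=tpl.center)
    if not candidate.evaluable:
        rec.evaluable = False
        rec.reason_unevaluable = candidate.reason
        return rec
    try:
        rec.improper = signed_improper(
            [res.atom(name).position for name in tpl.quadruple()]
        )
    except DegenerateGeometryError as exc:
        rec.evaluable = False
        rec.reason_unevaluable = f"degenerate geometry: {exc}"
        return rec
    rec.flagged = (rec.improper * tpl.expected_sign) < 0
    return rec


def check_structure(s: Structure,
                    cfg: Optional[DetectionConfig] = None,
                    templates: Iterable = DEFAULT_TEMPLATES) -> DetectionReport:
    """Full stereochemistry scan: every peptide bond and chiral center.

    Anomalies never raise out of the scan; degenerate or incomplete sites
    are carried in the report as unevaluable records.
    """
    cfg = cfg or DetectionConfig()
    report = DetectionReport(residues_total=s.residue_count)
    contributing: set = set()
    for cand in enumerate_peptide_bonds(s, cfg):
        rec = classify_peptide_bond(cand, cfg)
        report.peptide_bonds.append(rec)
        if rec.evaluable:
            contributing.add(rec.residue_i)
            contributing.add(rec.residue_j)
    for cand in enumerate_chiral_centers(s, templates, cfg):
        rec = evaluate_chiral_center(cand)
        report.chiral_centers.append(rec)
        if rec.evaluable:
            contributing.add(rec.residue)
    report.residues_checked = len(contributing)
    return report
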