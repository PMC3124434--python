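"""PDB-format reading and writing, plus the header records used for cross-validation.

The coordinate model is deliberately minimal: one model per structure, one
conformation per atom.  When a file contains several NMR-style models only
the first is kept, and when a residue carries alternate locations only the
first-encountered altLoc identifier is retained.  Header parsing covers the
records that annotate stereochemistry: CISPEP (per-bond cis-peptide
reports), CAVEAT (free-text structure-level warnings), REMARK 500 chirality
lines, and EXPDTA (experimental method).

Only the PDB dialect is supported: CISPEP/CAVEAT/REMARK 500/EXPDTA are all
PDB-format constructs, so the cross-validation this package performs has no
mmCIF equivalent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueId",
    "Structure",
    "CispepEntry",
    "HeaderAnnotations",
    "EmptyStructureError",
    "FieldOverflowError",
    "read_structure",
    "parse_header_annotations",
    "write_structure",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUES",
    "RNA_RESIDUES",
]


class EmptyStructureError(ValueError):
    """Input contained no parseable ATOM/HETATM coordinate record."""


class FieldOverflowError(ValueError):
    """An atom or residue field cannot be represented in PDB fixed columns."""


STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
DNA_RESIDUES = frozenset("DA DC DG DT DI".split())
RNA_RESIDUES = frozenset("A C G U I".split())


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")

    @property
    def is_hydrogen(self) -> bool:
        """Hydrogen by element symbol, with atom-name fallback for files
        lacking the element column (leading digits stripped first)."""
        el = self.element.strip().upper()
        if el:
            return el in ("H", "D")
        stripped = self.name.strip().lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")


#: (chain_id, seq_num, insertion_code) — the identity of a residue in a file
ResidueId = tuple


@dataclass
class Residue:
    name: str
    chain_id: str
    seq_num: int
    insertion_code: str
    atoms: list = field(default_factory=list)
    is_hetero: bool = False

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __contains__(self, name: str) -> bool:
        return self.atom(name) is not None

    @property
    def is_standard_amino_acid(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def is_nucleotide(self) -> bool:
        return self.name in DNA_RESIDUES or self.name in RNA_RESIDUES


@dataclass
class Structure:
    """One model's coordinates, organized as ordered chains of residues."""

    chains: dict = field(default_factory=dict)  # chain_id -> list[Residue]
    model_id: int = 1
    source_path: str = ""
    skipped_records: int = 0
    parse_warnings: list = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        """Atoms in serialized (chain, residue, atom) order."""
        for res in self.residues():
            yield from res.atoms

    @property
    def residue_count(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def get_residue(self, rid: ResidueId) -> Optional[Residue]:
        chain = self.chains.get(rid[0])
        if chain is None:
            return None
        for res in chain:
            if res.rid == tuple(rid):
                return res
        return None

    def atom_index_map(self) -> dict:
        """(residue id, atom name) -> 0-based index in serialized atom order."""
        index = {}
        for i, (res, atom) in enumerate(
            (res, atom) for res in self.residues() for atom in res.atoms
        ):
            index[(res.rid, atom.name)] = i
        return index


@dataclass(frozen=True)
class CispepEntry:
    res1_name: str
    res1_chain: str
    res1_seq: int
    res1_icode: str
    res2_name: str
    res2_chain: str
    res2_seq: int
    res2_icode: str
    angle: float

    @property
    def rid1(self) -> ResidueId:
        return (self.res1_chain, self.res1_seq, self.res1_icode)

    @property
    def rid2(self) -> ResidueId:
        return (self.res2_chain, self.res2_seq, self.res2_icode)


@dataclass
class HeaderAnnotations:
    cispep_entries: list = field(default_factory=list)
    caveat_present: bool = False
    caveat_text: str = ""
    remark500_chirality_lines: list = field(default_factory=list)
    experimental_method: str = "other"
    unparsed_lines: list = field(default_factory=list)


def _lines(pdb_text: Union[str, TextIO, Iterable]) -> list:
    if isinstance(pdb_text, str):
        return pdb_text.splitlines()
    if isinstance(pdb_text, io.IOBase) or hasattr(pdb_text, "read"):
        return pdb_text.read().splitlines()
    return list(pdb_text)


def _parse_coord_record(line: str) -> tuple:
    """Parse one ATOM/HETATM record from fixed columns; raises on malformed fields."""
    serial = int(line[6:11])
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    seq_num = int(line[22:26])
    icode = line[26].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occ = float(line[54:60]) if line[54:60].strip() else 1.0
    bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not name or not res_name:
        raise ValueError("blank atom or residue name")
    return serial, name, alt_loc, res_name, chain_id, seq_num, icode, (x, y, z), occ, bfac, element


def read_structure(pdb_text: Union[str, TextIO, Iterable], source_path: str = "") -> Structure:
    """Parse PDB coordinate records into a :class:`Structure`.

    Only the first model is retained; within each residue only the first
    alternate-location identifier encountered (plus blank-altLoc atoms) is
    kept.  Malformed fixed-column records are skipped with a warning carried
    on the returned structure.  Raises :class:`EmptyStructureError` when no
    coordinate record parses.
    """
    s = Structure(source_path=source_path)
    current: Optional[Residue] = None
    chosen_alt: dict = {}  # residue id -> first non-blank altLoc seen
    in_model = 0  # 0 = no MODEL seen yet, otherwise model number
    done = False
    n_atoms = 0
    for raw in _lines(pdb_text):
        rec = raw[:6].strip()
        if rec == "MODEL":
            if done:
                break
            try:
                in_model = int(raw[6:].split()[0])
            except (ValueError, IndexError):
                in_model = 1
            s.model_id = in_model
            continue
        if rec == "ENDMDL":
            done = True
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        if done:
            continue
        try:
            (serial, name, alt, res_name, chain_id, seq, icode, xyz, occ, bfac, element) = (
                _parse_coord_record(raw)
            )
        except (ValueError, IndexError) as exc:
            s.skipped_records += 1
            s.parse_warnings.append(f"skipped malformed record: {raw.rstrip()!r} ({exc})")
            continue
        rid = (chain_id, seq, icode)
        if alt:
            if rid not in chosen_alt:
                chosen_alt[rid] = alt
            if alt != chosen_alt[rid]:
                continue
        if current is None or current.rid != rid or current.name != res_name:
            existing = s.get_residue(rid) if (current is None or current.rid != rid) else None
            if existing is not None and existing.name == res_name:
                current = existing
            else:
                current = Residue(
                    name=res_name,
                    chain_id=chain_id,
                    seq_num=seq,
                    insertion_code=icode,
                    is_hetero=(rec == "HETATM"),
                )
                s.chains.setdefault(chain_id, []).append(current)
        if current.atom(name) is None:
            current.atoms.append(
                Atom(serial=serial, name=name, element=element, alt_loc=alt,
                     position=xyz, occupancy=occ, b_factor=bfac)
            )
        n_atoms += 1
    if n_atoms == 0:
        raise EmptyStructureError(f"no coordinate records in {source_path or 'input'}")
    return s


_METHOD_MAP = [
    ("X-RAY DIFFRACTION", "X-ray diffraction"),
    ("ELECTRON MICROSCOPY", "Electron microscopy"),
    ("ELECTRON CRYSTALLOGRAPHY", "Electron microscopy"),
    ("SOLUTION NMR", "Solution NMR"),
    ("SOLID-STATE NMR", "other"),
]


def parse_header_annotations(pdb_text: Union[str, TextIO, Iterable]) -> HeaderAnnotations:
    """Extract CISPEP, CAVEAT, REMARK 500 chirality lines, and EXPDTA.

    Never fatal: header lines that do not parse are retained verbatim in
    ``unparsed_lines``.
    """
    hdr = HeaderAnnotations()
    for raw in _lines(pdb_text):
        rec = raw[:6].strip()
        if rec == "CISPEP":
            try:
                entry = CispepEntry(
                    res1_name=raw[11:14].strip(),
                    res1_chain=raw[15].strip() or " ",
                    res1_seq=int(raw[17:21]),
                    res1_icode=raw[21].strip() if len(raw) > 21 else "",
                    res2_name=raw[25:28].strip(),
                    res2_chain=raw[29].strip() or " ",
                    res2_seq=int(raw[31:35]),
                    res2_icode=raw[35].strip() if len(raw) > 35 else "",
                    angle=float(raw[53:59]) if raw[53:59].strip() else 0.0,
                )
            except (ValueError, IndexError):
                hdr.unparsed_lines.append(raw.rstrip())
                continue
            hdr.cispep_entries.append(entry)
        elif rec == "CAVEAT":
            hdr.caveat_present = True
            text = raw[19:].strip() if len(raw) > 19 else ""
            hdr.caveat_text = (hdr.caveat_text + " " + text).strip()
        elif rec == "REMARK" and raw[7:10].strip() == "500":
            body = raw[10:].upper()
            if "CHIRAL" in body:
                hdr.remark500_chirality_lines.append(raw.rstrip())
        elif rec == "EXPDTA":
            body = raw[10:].upper()
            for key, label in _METHOD_MAP:
                if key in body:
                    hdr.experimental_method = label
                    break
            else:
                hdr.experimental_method = "other"
    return hdr


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name column alignment: 1-char elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    el = element.strip()
    if len(el) == 2 or (not el and len(name) == 4):
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_structure(s: Structure, header_lines: Optional[Iterable] = None) -> str:
    """Serialize a :class:`Structure` to PDB text.

    Coordinates are written %8.3f, so the read/write round trip is lossless
    to 0.001 A.  Optional ``header_lines`` (e.g. CISPEP/EXPDTA records) are
    emitted before the coordinate section.  Fields too wide for their fixed
    columns raise :class:`FieldOverflowError` naming the offender.
    """
    out = []
    if header_lines:
        out.extend(line.rstrip("\n") for line in header_lines)
    serial = 0
    for chain_id, residues in s.chains.items():
        if not residues:
            continue
        if len(str(chain_id)) > 1:
            raise FieldOverflowError(f"chain id {chain_id!r} does not fit one column")
        last = None
        for res in residues:
            if len(res.name) > 3:
                raise FieldOverflowError(f"residue name {res.name!r} exceeds 3 columns")
            if not -999 <= res.seq_num <= 9999:
                raise FieldOverflowError(f"residue number {res.seq_num} exceeds 4 columns")
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise FieldOverflowError(f"atom name {atom.name!r} exceeds 4 columns")
                serial += 1
                x, y, z = atom.position
                for label, v in (("x", x), ("y", y), ("z", z)):
                    if not -999.999 <= v <= 9999.999:
                        raise FieldOverflowError(
                            f"coordinate {label}={v:.3f} of atom {atom.name!r} "
                            f"in {res.name} {res.rid} does not fit %8.3f"
                        )
                rec = "HETATM" if res.is_hetero else "ATOM  "
                out.append(
                    f"{rec}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' ':1s}{res.name:>3s} {chain_id:1s}"
                    f"{res.seq_num:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
            last = res
        if last is not None and not last.is_hetero:
            serial += 1
            out.append(
                f"TER   {serial:5d}      {last.name:>3s} {chain_id:1s}"
                f"{last.seq_num:4d}{last.insertion_code or ' ':1s}"
            )
    out.append("END")
    return "\n".join(out) + "\n"
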