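"""Batch scanning, header cross-validation, and per-method aggregation.

A survey runs the stereochemistry scan over many PDB files, compares each
file's detections with its own header annotations (CISPEP records for cis
peptide bonds; CAVEAT and REMARK 500 records for chirality), and
aggregates totals per experimental method in the layout of an
archive-survey table: total errors, residues per error, structures
analyzed, structures with errors.

Cis peptide bonds are matched per bond on the full residue identifiers
(chain, sequence number, insertion code) of both partners.  Chirality is
cross-validated at structure level only: CAVEAT records are free format
and chirality errors are rarely itemized there, so the comparison is
"flags present" versus "header evidence present" (any CAVEAT, or any
REMARK 500 chirality line).

Surveys over large collections are resumable: per-file results can be
cached as JSON lines keyed by file checksum, so an interrupted run picks
up where it stopped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .stereo_detect import DetectionConfig, DetectionReport, check_structure
from .structure_io import HeaderAnnotations, parse_header_annotations, read_structure

__all__ = [
    "StructureResult",
    "DiscrepancyItem",
    "SurveyRow",
    "survey_structures",
    "compare_with_header",
    "aggregate_by_method",
    "survey_rows_to_tsv",
    "results_to_tsv",
]

logger = logging.getLogger(__name__)

DISCREPANCY_CATEGORIES = (
    "unreported_cis",
    "header_only_cis",
    "unreported_chirality",
    "header_only_chirality",
)


@dataclass
class DiscrepancyItem:
    category: str
    site: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in DISCREPANCY_CATEGORIES:
            raise ValueError(f"unknown discrepancy category {self.category!r}")


@dataclass
class StructureResult:
    source: str
    experimental_method: str = "other"
    residues_checked: int = 0
    residues_total: int = 0
    cis_count: int = 0
    chirality_error_count: int = 0
    unevaluable_bond_count: int = 0
    unevaluable_center_count: int = 0
    discrepancies: list = field(default_factory=list)
    parse_failed: bool = False
    error_message: str = ""


@dataclass
class SurveyRow:
    method: str
    total_errors: int
    residues_per_error: Optional[int]
    structures_analyzed: int
    structures_with_errors: int
    percent_with_errors: int


def _rid_str(rid) -> str:
    chain, seq, icode = rid
    return f"{chain}:{seq}{icode}"


def compare_with_header(report: DetectionReport, hdr: HeaderAnnotations) -> list:
    """Cross-validate one structure's detections against its own header.

    Returns a list of :class:`DiscrepancyItem`: detected cis bonds missing
    from CISPEP records (``unreported_cis``), CISPEP entries with no
    detected cis bond (``header_only_cis``), and the structure-level
    chirality mismatches (``unreported_chirality`` /
    ``header_only_chirality``).
    """
    out: list = []
    detected = {
        (tuple(b.residue_i), tuple(b.residue_j)): b for b in report.peptide_bonds if b.is_cis
    }
    reported = {(e.rid1, e.rid2): e for e in hdr.cispep_entries}
    for key, bond in detected.items():
        if key not in reported:
            out.append(
                DiscrepancyItem(
                    "unreported_cis",
                    f"{_rid_str(key[0])}-{_rid_str(key[1])}",
                    f"omega'={bond.omega_prime:.2f} deg, no CISPEP record",
                )
            )
    for key, entry in reported.items():
        if key not in detected:
            out.append(
                DiscrepancyItem(
                    "header_only_cis",
                    f"{_rid_str(key[0])}-{_rid_str(key[1])}",
                    f"CISPEP reports {entry.angle:.2f} deg but no cis bond detected",
                )
            )
    flags = report.chirality_error_count > 0
    evidence = hdr.caveat_present or bool(hdr.remark500_chirality_lines)
    if flags and not evidence:
        sites = ",".join(
            f"{_rid_str(c.residue)}:{c.center}" for c in report.flagged_centers()
        )
        out.append(
            DiscrepancyItem("unreported_chirality", sites,
                            "chirality flags without CAVEAT/REMARK 500 annotation")
        )
    elif evidence and not flags:
        out.append(
            DiscrepancyItem("header_only_chirality", "structure",
                            "CAVEAT/REMARK 500 chirality annotation but no flagged center")
        )
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _analyze_one(path: Path, cfg: DetectionConfig) -> StructureResult:
    try:
        text = path.read_text(errors="replace")
        structure = read_structure(text, source_path=str(path))
        hdr = parse_header_annotations(text)
    except Exception as exc:  # any unreadable/coordinate-free file
        return StructureResult(source=str(path), parse_failed=True,
                               error_message=str(exc))
    report = check_structure(structure, cfg)
    return StructureResult(
        source=str(path),
        experimental_method=hdr.experimental_method,
        residues_checked=report.residues_checked,
        residues_total=report.residues_total,
        cis_count=report.cis_count,
        chirality_error_count=report.chirality_error_count,
        unevaluable_bond_count=report.unevaluable_bond_count,
        unevaluable_center_count=report.unevaluable_center_count,
        discrepancies=compare_with_header(report, hdr),
    )


def survey_structures(paths: Iterable, cfg: Optional[DetectionConfig] = None,
                      cache_path=None) -> list:
    """Scan many files independently; one :class:`StructureResult` per file.

    Unreadable files yield ``parse_failed`` results rather than aborting
    the survey.  When ``cache_path`` is given, results are appended there
    as JSON lines keyed by file checksum and reused on a rerun.
    """
    cfg = cfg or DetectionConfig()
    cache: dict = {}
    cache_file = Path(cache_path) if cache_path else None
    if cache_file is not None and cache_file.exists():
        for line in cache_file.read_text().splitlines():
            try:
                entry = json.loads(line)
                cache[entry["checksum"]] = entry["result"]
            except (json.JSONDecodeError, KeyError):
                continue
    results: list = []
    for raw_path in paths:
        path = Path(raw_path)
        key = None
        if cache_file is not None and path.exists():
            key = _checksum(path)
            if key in cache:
                stored = dict(cache[key])
                stored["discrepancies"] = [
                    DiscrepancyItem(**d) for d in stored.get("discrepancies", [])
                ]
                results.append(StructureResult(**stored))
                continue
        res = _analyze_one(path, cfg)
        if res.parse_failed:
            logger.warning("parse failed for %s: %s", path, res.error_message)
        else:
            logger.info("%s: %d cis, %d chirality flags", path,
                        res.cis_count, res.chirality_error_count)
        results.append(res)
        if cache_file is not None and key is not None:
            with cache_file.open("a") as fh:
                fh.write(json.dumps({"checksum": key, "result": asdict(res)}) + "\n")
    return results


def aggregate_by_method(results: Sequence[StructureResult],
                        kind: str = "all") -> list:
    """One :class:`SurveyRow` per experimental method, plus an "All" row.

    ``kind`` selects which errors are totalled: ``"cis"``, ``"chirality"``
    or ``"all"`` (their sum).  ``residues_per_error`` is the ratio of total
    residues checked to total errors, rounded to integer, and absent when
    there are no errors; the percentage of structures with errors is
    rounded to integer percent.  Parse failures are excluded.
    """
    if kind not in ("cis", "chirality", "all"):
        raise ValueError("kind must be 'cis', 'chirality' or 'all'")

    def errors_of(r: StructureResult) -> int:
        if kind == "cis":
            return r.cis_count
        if kind == "chirality":
            return r.chirality_error_count
        return r.cis_count + r.chirality_error_count

    ok = [r for r in results if not r.parse_failed]
    methods = sorted({r.experimental_method for r in ok})

    def row(label: str, subset) -> SurveyRow:
        total = sum(errors_of(r) for r in subset)
        residues = sum(r.residues_checked for r in subset)
        n = len(subset)
        with_err = sum(1 for r in subset if errors_of(r) > 0)
        return SurveyRow(
            method=label,
            total_errors=total,
            residues_per_error=round(residues / total) if total else None,
            structures_analyzed=n,
            structures_with_errors=with_err,
            percent_with_errors=round(100.0 * with_err / n) if n else 0,
        )

    rows = [row("All", ok)]
    rows.extend(row(m, [r for r in ok if r.experimental_method == m]) for m in methods)
    return rows


def survey_rows_to_tsv(rows: Sequence[SurveyRow]) -> str:
    out = ["method\ttotal_errors\tresidues_per_error\tstructures_analyzed"
           "\tstructures_with_errors\tpercent_with_errors"]
    for r in rows:
        rpe = "" if r.residues_per_error is None else str(r.residues_per_error)
        out.append(f"{r.method}\t{r.total_errors}\t{rpe}\t{r.structures_analyzed}"
                   f"\t{r.structures_with_errors}\t{r.percent_with_errors}")
    return "\n".join(out) + "\n"


def results_to_tsv(results: Sequence[StructureResult]) -> str:
    out = ["source\tmethod\tresidues_checked\tcis_count\tchirality_error_count"
           "\tunevaluable_bonds\tunevaluable_centers\tdiscrepancies\tparse_failed"]
    for r in results:
        disc = ";".join(f"{d.category}@{d.site}" for d in r.discrepancies)
        out.append(
            f"{r.source}\t{r.experimental_method}\t{r.residues_checked}"
            f"\t{r.cis_count}\t{r.chirality_error_count}\t{r.unevaluable_bond_count}"
            f"\t{r.unevaluable_center_count}\t{disc}\t{int(r.parse_failed)}"
        )
    return "\n".join(out) + "\n"
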