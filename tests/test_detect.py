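"""Detection: peptide-bond enumeration/classification and chirality evaluation."""

import numpy as np
import pytest

from stereocheck.fixtures import BuildSpec, build_peptide, mirror_structure, nucleotide_fixture
from stereocheck.stereo_detect import (
    DEFAULT_TEMPLATES,
    DetectionConfig,
    check_structure,
    classify_peptide_bond,
    enumerate_chiral_centers,
    enumerate_peptide_bonds,
)
from stereocheck.structure_io import read_structure, write_structure


class TestEnumeratePeptideBonds:
    def test_helix_has_n_minus_one_evaluable_bonds(self, clean_helix):
        candidates = enumerate_peptide_bonds(clean_helix)
        assert len(candidates) == 14
        assert all(c.evaluable for c in candidates)

    def test_chain_break_excluded_by_distance(self, clean_helix):
        import copy

        s = copy.deepcopy(clean_helix)
        res = s.get_residue(("A", 8, ""))
        for atom in res.atoms:
            atom.position = atom.position + np.array([50.0, 0.0, 0.0])
        candidates = enumerate_peptide_bonds(s)
        pairs = {(c.residue_i.seq_num, c.residue_j.seq_num) for c in candidates}
        assert (7, 8) not in pairs and (8, 9) not in pairs
        assert len(candidates) == 12

    def test_missing_oxygen_marks_bond_unevaluable(self, clean_helix):
        import copy

        s = copy.deepcopy(clean_helix)
        res = s.get_residue(("A", 8, ""))
        res.atoms = [a for a in res.atoms if a.name != "O"]
        candidates = enumerate_peptide_bonds(s)
        bad = [c for c in candidates if not c.evaluable]
        assert len(bad) == 1
        assert bad[0].residue_i.seq_num == 8
        assert "O" in bad[0].reason

    def test_capping_groups_are_not_peptide_neighbors(self):
        s = build_peptide(BuildSpec("AAQA", capped=True))
        candidates = enumerate_peptide_bonds(s)
        assert len(candidates) == 3  # ACE/NH2 caps contribute no bonds


class TestClassifyPeptideBond:
    def build_bond(self, omega):
        s = build_peptide(BuildSpec("AA", omega=omega))
        (cand,) = enumerate_peptide_bonds(s)
        return classify_peptide_bond(cand)

    def test_ideal_trans_not_cis(self):
        rec = self.build_bond(180.0)
        assert abs(rec.omega_prime) < 1e-6
        assert not rec.is_cis

    def test_ideal_cis_flagged(self):
        rec = self.build_bond(0.0)
        assert abs(rec.omega_prime) == pytest.approx(180.0)
        assert rec.is_cis

    @pytest.mark.parametrize(
        "omega_prime_abs,expected",
        [(84.0, False), (85.0, False), (86.0, True)],  # strictly larger than 85
    )
    def test_threshold_is_strict(self, omega_prime_abs, expected):
        # built structures satisfy omega' = omega - 180 exactly
        rec = self.build_bond(180.0 - omega_prime_abs)
        assert abs(rec.omega_prime) == pytest.approx(omega_prime_abs, abs=1e-9)
        assert rec.is_cis is expected

    def test_pre_proline_annotated(self):
        s = build_peptide(BuildSpec("APA", omega=0.0))
        records = [classify_peptide_bond(c) for c in enumerate_peptide_bonds(s)]
        assert [r.pre_proline for r in records] == [True, False]
        assert all(r.is_cis for r in records)


class TestEnumerateChiralCenters:
    def test_helix_has_one_center_per_residue(self, clean_helix):
        candidates = enumerate_chiral_centers(clean_helix)
        assert len(candidates) == 15
        assert {c.template.center for c in candidates} == {"CA"}

    def test_glycine_contributes_no_center(self):
        s = build_peptide(BuildSpec("AGA"))
        candidates = enumerate_chiral_centers(s)
        assert len(candidates) == 2
        assert all(c.residue.name != "GLY" for c in candidates)

    def test_thr_ile_contribute_beta_centers(self):
        s = build_peptide(BuildSpec("ATIA"))
        candidates = enumerate_chiral_centers(s)
        centers = sorted((c.residue.name, c.template.center) for c in candidates)
        assert centers == [
            ("ALA", "CA"), ("ALA", "CA"),
            ("ILE", "CA"), ("ILE", "CB"),
            ("THR", "CA"), ("THR", "CB"),
        ]

    @pytest.mark.parametrize("kind,expected", [("RNA", 4), ("DNA", 3)])
    def test_nucleotide_sugar_centers(self, kind, expected):
        s = read_structure(nucleotide_fixture(kind))
        candidates = enumerate_chiral_centers(s)
        names = {c.template.center for c in candidates}
        assert len(candidates) == expected
        assert ("C2'" in names) == (kind == "RNA")

    def test_missing_template_atom_unevaluable(self, clean_helix):
        import copy

        s = copy.deepcopy(clean_helix)
        res = s.get_residue(("A", 8, ""))
        res.atoms = [a for a in res.atoms if a.name != "CB"]
        report = check_structure(s)
        bad = [c for c in report.chiral_centers if not c.evaluable]
        assert len(bad) == 1 and "CB" in bad[0].reason_unevaluable


class TestCheckStructure:
    def test_clean_helix_no_flags(self, clean_helix):
        report = check_structure(clean_helix)
        assert report.cis_count == 0
        assert report.chirality_error_count == 0
        assert report.residues_checked == 15

    def test_injected_cis_detected_at_site(self, one_cis_helix):
        report = check_structure(one_cis_helix)
        assert report.cis_count == 1
        bond = report.cis_bonds()[0]
        assert (bond.residue_i, bond.residue_j) == (("A", 8, ""), ("A", 9, ""))
        assert (bond.residue_i_name, bond.residue_j_name) == ("GLN", "ALA")

    def test_injected_d_center_detected_at_site(self, one_d_helix):
        report = check_structure(one_d_helix)
        assert report.chirality_error_count == 1
        center = report.flagged_centers()[0]
        assert center.residue == ("A", 8, "")
        assert center.improper < 0

    def test_combined_injection_exactness(self, combined_helix):
        report = check_structure(combined_helix)
        assert report.cis_count == 1
        assert report.chirality_error_count == 1
        assert report.cis_bonds()[0].residue_i == ("A", 8, "")
        assert report.flagged_centers()[0].residue == ("A", 8, "")

    def test_mirror_flags_all_centers_keeps_cis_verdicts(self, combined_helix):
        mirrored = mirror_structure(combined_helix)
        before = check_structure(combined_helix)
        after = check_structure(mirrored)
        evaluable = [c for c in after.chiral_centers if c.evaluable]
        assert all(c.flagged == (not b.flagged)
                   for b, c in zip(before.chiral_centers, evaluable))
        assert [b.is_cis for b in before.peptide_bonds] == [
            b.is_cis for b in after.peptide_bonds
        ]

    def test_determinism_on_identical_text(self, combined_helix):
        text = write_structure(combined_helix)
        r1 = check_structure(read_structure(text))
        r2 = check_structure(read_structure(text))
        assert r1.to_json() == r2.to_json()

    def test_report_serializations_include_counts(self, combined_helix):
        report = check_structure(combined_helix)
        tsv = report.to_tsv()
        assert tsv.count("\tcis\t") == 1
        assert tsv.count("\tflagged\t") == 1
        import json

        payload = json.loads(report.to_json())
        assert payload["cis_count"] == 1
        assert payload["chirality_error_count"] == 1
        assert len(payload["peptide_bonds"]) == 14
        assert len(payload["chiral_centers"]) == 15


class TestMirrorSymmetrySuite:
    def test_fifty_random_specs(self, rng):
        letters = np.array(list("AGQTIP"))
        for _ in range(50):
            n = int(rng.integers(3, 10))
            seq = "".join(rng.choice(letters, size=n))
            spec = BuildSpec(
                sequence=seq,
                phi=float(rng.uniform(-150, -50)),
                psi=float(rng.uniform(-60, 150)),
            )
            s = build_peptide(spec)
            plain = check_structure(s)
            mirrored = check_structure(mirror_structure(s))
            for b, a in zip(plain.chiral_centers, mirrored.chiral_centers):
                if a.evaluable:
                    assert a.flagged == (not b.flagged)
            assert [b.is_cis for b in plain.peptide_bonds] == [
                b.is_cis for b in mirrored.peptide_bonds
            ]


class TestOracleEquivalence:
    def test_improper_sign_equals_triple_product_over_1000_draws(self):
        """The template improper verdict must agree with a CIP-style signed
        triple product on randomized tetrahedral arrangements."""
        from stereocheck.geometry import signed_improper
        from stereocheck.structure_io import Atom, Residue, Structure
        from stereocheck.stereo_detect import evaluate_chiral_center, _CenterCandidate

        template = next(t for t in DEFAULT_TEMPLATES if t.center == "CA")
        rng = np.random.default_rng(1234)
        agree = 0
        total = 0
        while total < 1000:
            center = rng.normal(size=3) * 5.0
            subs = center + rng.normal(size=(3, 3)) * 1.5
            det = np.linalg.det(subs - center)
            if abs(det) < 1e-4:
                continue
            res = Residue("ALA", "A", 1, "")
            res.atoms = [
                Atom(1, "N", "N", "", subs[0]),
                Atom(2, "CA", "C", "", center),
                Atom(3, "C", "C", "", subs[1]),
                Atom(4, "CB", "C", "", subs[2]),
            ]
            rec = evaluate_chiral_center(_CenterCandidate(res, template))
            oracle_flag = np.sign(det) != template.expected_sign
            agree += rec.flagged == oracle_flag
            total += 1
        assert agree == total


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(omega_prime_threshold=0.0)
    with pytest.raises(ValueError):
        DetectionConfig(omega_prime_threshold=180.0)
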