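"""Correction moves, local regularization, and restraint generation."""

import warnings

import numpy as np
import pytest

from stereocheck._ideal import PEPTIDE_CN, ideal_bond_length
from stereocheck.fixtures import BuildSpec, build_peptide
from stereocheck.geometry import dihedral_angle
from stereocheck.stereo_correct import (
    MissingAtomError,
    RestraintSpec,
    correct_chirality,
    correct_peptide_bond,
    flip_chirality,
    flip_peptide_bond,
    generate_restraints,
    omega_restraint,
    parse_extrabonds,
    regularize_local,
    write_extrabonds,
)
from stereocheck.stereo_detect import check_structure


def bond_length_deviations(s):
    """Max deviation of backbone/side-chain bond lengths from ideal."""
    from stereocheck._ideal import SIDECHAIN_BONDS, residue_bonds

    worst = 0.0
    for chain in s.chains.values():
        for res in chain:
            if res.name not in SIDECHAIN_BONDS:
                continue
            for a, b in residue_bonds(res.name):
                aa, ab = res.atom(a), res.atom(b)
                if aa is None or ab is None or (res.name, a) == ("PRO", "CD"):
                    continue
                d = np.linalg.norm(aa.position - ab.position)
                worst = max(worst, abs(d - ideal_bond_length(res.name, a, b)))
        for ri, rj in zip(chain, chain[1:]):
            c, n = ri.atom("C"), rj.atom("N")
            if c is not None and n is not None:
                d = np.linalg.norm(c.position - n.position)
                if d < 2.0:
                    worst = max(worst, abs(d - PEPTIDE_CN))
    return worst


class TestFlipPeptideBond:
    def test_oxygen_reflected_through_carbon(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        flipped = flip_peptide_bond(one_cis_helix, bond, "O")
        res = flipped.get_residue(bond.residue_i)
        old = one_cis_helix.get_residue(bond.residue_i)
        expected = 2 * old.atom("C").position - old.atom("O").position
        assert np.allclose(res.atom("O").position, expected)
        # everything else untouched
        others = [
            (a, b)
            for ra, rb in zip(one_cis_helix.residues(), flipped.residues())
            for a, b in zip(ra.atoms, rb.atoms)
            if not (ra.rid == bond.residue_i and a.name == "O")
        ]
        assert all(np.array_equal(a.position, b.position) for a, b in others)

    def test_hydrogen_reflected_through_nitrogen(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        flipped = flip_peptide_bond(one_cis_helix, bond, "H")
        res_j_old = one_cis_helix.get_residue(bond.residue_j)
        res_j_new = flipped.get_residue(bond.residue_j)
        expected = 2 * res_j_old.atom("N").position - res_j_old.atom("H").position
        assert np.allclose(res_j_new.atom("H").position, expected)

    def test_flip_toggles_classification_on_planar_input(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        flipped = flip_peptide_bond(one_cis_helix, bond, "O")
        report = check_structure(flipped)
        refreshed = [
            b for b in report.peptide_bonds
            if (b.residue_i, b.residue_j) == (bond.residue_i, bond.residue_j)
        ][0]
        assert not refreshed.is_cis

    def test_moving_calpha_refused(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        with pytest.raises(ValueError, match="not allowed"):
            flip_peptide_bond(one_cis_helix, bond, "CA")

    def test_missing_hydrogen_raises_naming_it(self):
        s = build_peptide(BuildSpec(cis_bonds=(2,), include_hydrogens=False))
        bond = check_structure(s).cis_bonds()[0]
        with pytest.raises(MissingAtomError, match="H"):
            flip_peptide_bond(s, bond, "H")


class TestFlipChirality:
    def test_hydrogen_reflected_through_center(self, one_d_helix):
        center = check_structure(one_d_helix).flagged_centers()[0]
        flipped = flip_chirality(one_d_helix, center)
        old = one_d_helix.get_residue(center.residue)
        new = flipped.get_residue(center.residue)
        expected = 2 * old.atom("CA").position - old.atom("HA").position
        assert np.allclose(new.atom("HA").position, expected)

    def test_hydrogen_free_model_raises(self):
        s = build_peptide(BuildSpec(d_residues=(8,), include_hydrogens=False))
        center = check_structure(s).flagged_centers()[0]
        with pytest.raises(MissingAtomError, match="hydrogens"):
            flip_chirality(s, center)


class TestRegularizeLocal:
    def test_already_ideal_input_unchanged(self, clean_helix):
        result = regularize_local(clean_helix, ("A", 8, ""), cutoff=8.0)
        assert result.converged
        for a, b in zip(clean_helix.atoms(), result.structure.atoms()):
            assert np.linalg.norm(a.position - b.position) < 1e-3

    def test_atoms_beyond_cutoff_bit_identical(self):
        # extended chain so that the cutoff actually excludes residues
        s = build_peptide(BuildSpec("AAAAAAAAAAAA", phi=-139.0, psi=135.0,
                                    cis_bonds=(6,)))
        bond = check_structure(s).cis_bonds()[0]
        result = correct_peptide_bond(s, bond, move="O", cutoff=5.0)
        frozen = [rid for rid in (r.rid for r in s.residues())
                  if rid not in result.mobile_residues]
        assert frozen, "cutoff did not exclude any residue"
        for rid in frozen:
            before = s.get_residue(rid)
            after = result.structure.get_residue(rid)
            for a, b in zip(before.atoms, after.atoms):
                assert np.array_equal(a.position, b.position)

    def test_invalid_cutoff_rejected(self, clean_helix):
        with pytest.raises(ValueError):
            regularize_local(clean_helix, ("A", 8, ""), cutoff=0.0)

    def test_nonconvergence_warns_and_flags(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        flipped = flip_peptide_bond(one_cis_helix, bond, "O")
        target = omega_restraint(flipped, bond, 180.0)
        with pytest.warns(UserWarning, match="did not converge"):
            result = regularize_local(flipped, bond.residue_i, targets=[target],
                                      max_iterations=3)
        assert not result.converged
        assert result.max_gradient > 0.1


class TestCorrectionRoundTrip:
    def test_cis_bond_corrected(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        result = correct_peptide_bond(one_cis_helix, bond, move="O")
        assert result.converged
        report = check_structure(result.structure)
        assert report.cis_count == 0
        assert report.chirality_error_count == 0
        assert bond_length_deviations(result.structure) < 0.05
        res_i = result.structure.get_residue(bond.residue_i)
        res_j = result.structure.get_residue(bond.residue_j)
        omega_prime = dihedral_angle(
            res_i.atom("O").position, res_i.atom("C").position,
            res_j.atom("N").position, res_j.atom("CA").position,
        )
        assert abs(omega_prime) < 10.0

    def test_cis_bond_corrected_via_hydrogen_move(self, one_cis_helix):
        bond = check_structure(one_cis_helix).cis_bonds()[0]
        result = correct_peptide_bond(one_cis_helix, bond, move="H")
        report = check_structure(result.structure)
        assert report.cis_count == 0 and report.chirality_error_count == 0

    def test_d_center_corrected(self, one_d_helix):
        center = check_structure(one_d_helix).flagged_centers()[0]
        result = correct_chirality(one_d_helix, center)
        assert result.converged
        report = check_structure(result.structure)
        assert report.chirality_error_count == 0
        assert report.cis_count == 0
        assert bond_length_deviations(result.structure) < 0.05

    def test_combined_fixture_fully_corrected(self, combined_helix):
        report = check_structure(combined_helix)
        s = combined_helix
        s = correct_peptide_bond(s, report.cis_bonds()[0], move="O").structure
        center = check_structure(s).flagged_centers()[0]
        s = correct_chirality(s, center).structure
        final = check_structure(s)
        assert final.anomaly_count == 0


class TestRestraints:
    def test_clean_helix_counts(self, clean_helix):
        report = check_structure(clean_helix)
        specs = generate_restraints(clean_helix, report)
        dihedrals = [r for r in specs if r.kind == "dihedral"]
        impropers = [r for r in specs if r.kind == "improper"]
        assert len(dihedrals) == 14
        assert len(impropers) == 15
        assert all(r.reference_angle == 180.0 for r in dihedrals)

    def test_kept_cis_bond_gets_zero_reference(self, one_cis_helix):
        report = check_structure(one_cis_helix)
        specs = generate_restraints(one_cis_helix, report)
        dihedrals = [r for r in specs if r.kind == "dihedral"]
        refs = sorted(r.reference_angle for r in dihedrals)
        assert refs.count(0.0) == 1 and refs.count(180.0) == 13

    def test_indices_are_valid_serialized_positions(self, clean_helix):
        report = check_structure(clean_helix)
        specs = generate_restraints(clean_helix, report)
        n_atoms = sum(1 for _ in clean_helix.atoms())
        names = [a.name for a in clean_helix.atoms()]
        for r in specs:
            assert all(0 <= i < n_atoms for i in r.atom_indices)
        omega_names = [names[i] for i in specs[0].atom_indices]
        assert omega_names == ["CA", "C", "N", "CA"]

    def test_empty_structure_yields_empty_collection(self):
        from stereocheck.structure_io import Structure
        from stereocheck.stereo_detect import DetectionReport

        assert generate_restraints(Structure(), DetectionReport()) == []

    def test_minimizing_under_restraints_preserves_classification(self, clean_helix):
        report = check_structure(clean_helix)
        specs = generate_restraints(clean_helix, report)
        result = regularize_local(clean_helix, ("A", 8, ""), cutoff=1e6,
                                  targets=specs)
        after = check_structure(result.structure)
        assert [b.is_cis for b in report.peptide_bonds] == [
            b.is_cis for b in after.peptide_bonds
        ]
        assert [c.flagged for c in report.chiral_centers] == [
            c.flagged for c in after.chiral_centers
        ]


class TestExtraBonds:
    def test_single_line_format(self):
        spec = RestraintSpec("dihedral", (4, 6, 11, 13), 200.0, 180.0)
        text = write_extrabonds([spec])
        assert text == "dihedral 4 6 11 13 200.0 180.0\n"

    def test_round_trip_lossless(self, clean_helix):
        report = check_structure(clean_helix)
        specs = generate_restraints(clean_helix, report)
        assert parse_extrabonds(write_extrabonds(specs)) == specs

    def test_mixed_kinds_preserve_order(self):
        specs = [
            RestraintSpec("improper", (0, 1, 2, 3), 150.0, 35.5),
            RestraintSpec("dihedral", (4, 5, 6, 7), 200.0, 0.0),
            RestraintSpec("improper", (8, 9, 10, 11), 200.0, -120.25),
        ]
        assert parse_extrabonds(write_extrabonds(specs)) == specs

    def test_validation_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            RestraintSpec("torsion", (0, 1, 2, 3))
        with pytest.raises(ValueError):
            RestraintSpec("dihedral", (0, 1, 2, 2))
        with pytest.raises(ValueError):
            RestraintSpec("dihedral", (0, 1, 2))
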