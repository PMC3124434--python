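# stereocheck

Detect, correct, and prevent stereochemical errors — chirality flips and
*cis* peptide bonds — in protein and nucleic acid structures destined for
molecular dynamics simulation.

Biomolecular force fields contain no terms that enforce stereochemistry:
they support a D-amino acid or a *cis* peptide bond just as happily as the
correct L/*trans* form, so an error in the input structure persists through
an entire simulation and can wreck secondary structure. Such errors creep
in through homology modelling, aggressive system-preparation minimization,
flexible fitting into low-resolution maps, and occasionally the deposited
experimental model itself. `stereocheck` is for simulators and modellers
who want a scriptable check-inspect-correct loop before production runs.

## What it computes

**Cis peptide bonds.** The backbone dihedral ω over
Cα(n), C(n), N(n+1), Cα(n+1) is ≈180° for *trans* and ≈0° for *cis*
bonds. Detection instead uses the equivalent dihedral
**ω′ = ∠(O(n), C(n), N(n+1), Cα(n+1))**, which is built from atom names
unique within the two residues and is ≈0° for *trans*, ≈180° for *cis*. A
bond is flagged when **|ω′| > 85°** (strict inequality; the magnitude is
used because a torsion's sign carries no cis/trans information).
Pre-proline bonds are flagged but annotated, since Xaa-Pro *cis* bonds are
usually genuine.

**Chirality.** Every supported chiral center (Cα of all standard amino
acids except glycine, Cβ of Thr/Ile, sugar C1′/C3′/C4′ of nucleotides plus
C2′ of ribonucleotides) carries a signed **improper dihedral** over
non-hydrogen substituents with the chiral atom inside the quadruple. The
substituent orderings are calibrated so every naturally occurring
configuration gives a *positive* improper; **a negative improper flags an
unusual configuration**. The improper's sign provably equals the sign of
the triple product det[s₁−c, s₂−c, s₃−c] — the classic orientation test.

**Correction** is deliberately semi-automatic (D-amino acids and *cis*
prolines occur in nature, so nothing is auto-fixed): the user picks a site,
the tool reflects one peripheral atom (carbonyl O through its C, or an
amide/α hydrogen through its N/Cα — Cα atoms never move), then locally
minimizes a harmonic bonded-term model under a target-state dihedral
restraint. Atoms of residues outside the cutoff (default 8 Å) are
bit-identical before and after.

**Prevention.** Harmonic restraints preserving the current isomerization
state of every bond and center can be exported in the extra-bonds text
dialect (`dihedral i j k l k_force ref_angle`, 0-based indices) for use
during rough relaxation stages; remove them before production runs.

A batch **survey** mode scans many PDB files, cross-validates detections
against the files' own CISPEP / CAVEAT / REMARK 500 headers, and
aggregates error totals, residues-per-error ratios and affected-structure
percentages per experimental method (EXPDTA).

## Worked example

The package ships a synthetic-structure builder (sequence default: the
15-residue helix AAQAAAAQAAAAQAA) with injectable perturbations, used here
to make a structure with a D-Gln8 and a *cis* Gln8-Ala9 bond:

```console
$ stereocheck build-fixtures demo
wrote 8 fixture files to demo

$ stereocheck check demo/combined.pdb
cis peptide bond GLN A:8 - ALA A:9 omega'=179.99
chirality flag GLN A:8 at CA improper=-122.85
residues checked: 15; cis bonds: 1; chirality flags: 1; unevaluable: 0 bonds, 0 centers
$ echo $?
1
```

ω′ of 179.99° is a textbook *cis* bond (trans would be ≈0°), and the
negative improper at Gln8 marks the D-center. Exit status 1 means
"anomalies found", so the recommended repeat-until-clean loop is
scriptable. Correct both sites and re-check:

```console
$ stereocheck fix demo/combined.pdb -o demo/fixed.pdb \
      --flip-bond A:8-A:9:O --flip-center A:8:CA
wrote demo/fixed.pdb; remaining anomalies: 0

$ stereocheck check demo/fixed.pdb; echo $?
residues checked: 15; cis bonds: 0; chirality flags: 0; unevaluable: 0 bonds, 0 centers
0
```

Export preserving restraints (14 ω dihedrals + 15 Cα impropers here):

```console
$ stereocheck restraints demo/fixed.pdb -o demo/extra.txt
wrote 29 restraints to demo/extra.txt
$ head -2 demo/extra.txt
dihedral 1 2 6 7 200.0 180.0
dihedral 7 8 13 14 200.0 180.0
```

Survey a directory and aggregate per method (the fixture battery carries
crafted EXPDTA headers):

```console
$ stereocheck survey demo --kind cis
method              total_errors  residues_per_error  structures_analyzed  structures_with_errors  percent_with_errors
All                 3             40                  8                    3                       38
Electron microscopy 1             15                  1                    1                       100
Solution NMR        0                                 1                    0                       0
X-ray diffraction   2             45                  6                    2                       33
```

Every number is recomputed from the files: `residues_per_error` is total
residues checked divided by total errors, and the "All" row is the column
sum over methods.

The same operations are available as a library
(`stereocheck.check_structure`, `correct_peptide_bond`,
`generate_restraints`, `build_peptide`, ...); see `docs/methods.md` for the
model details and parameter choices.

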