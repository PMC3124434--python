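# Methods

## Detection model

### Cis peptide bonds

A peptide bond's isomer is determined by the torsion about the C(n)-N(n+1)
partial double bond. The conventional measure is
ω = ∠(Cα(n), C(n), N(n+1), Cα(n+1)); detection here uses
ω′ = ∠(O(n), C(n), N(n+1), Cα(n+1)), whose four atom names are unique
within the residue pair. Because the carbonyl O and the preceding Cα are
anti across the Cα-C axis in a planar peptide group, ω′ ≈ ω − 180°: a
*trans* bond has ω′ ≈ 0 and a *cis* bond |ω′| ≈ 180. A bond is classified
cis when **|ω′| > 85°**, a strict inequality. The threshold is applied to
the magnitude only: torsion sign depends purely on the viewing convention
and carries no isomer information. The 85° value leaves a wide margin on
both sides of the two ideal states; bonds near ±90° are pathologically
distorted whichever way they are counted.

Bond candidates are consecutive standard amino-acid residues within a
chain whose C(n)-N(n+1) distance is ≤ 2.0 Å (default). Pairs beyond the
cutoff are chain breaks and produce no candidate; candidates missing any
of the five required heavy atoms (Cα, C, O of n; N, Cα of n+1) are
reported as unevaluable with the missing atom named, never silently
dropped. HETATM residues are checked only when they carry a standard
residue name — cofactor and ligand chirality is out of scope. Capping
groups (ACE/NH2) and other non-standard names are skipped as peptide
neighbours.

### Chirality

Each supported center is tested with a signed improper dihedral over
non-hydrogen substituents, measured on the quadruple
(s₁, center, s₂, s₃). With that ordering the improper's sign equals the
sign of the triple product det[s₁−c, s₂−c, s₃−c] (verified numerically
over thousands of random arrangements, and enforced by a dedicated oracle
test), so the improper is exactly the classic signed-volume orientation
test expressed as an angle.

Substituent orderings per template were calibrated once against
CIP-correct 3D reference models and frozen:

| residues           | center | quadruple (s₁, c, s₂, s₃) | natural sign |
|--------------------|--------|---------------------------|--------------|
| amino acids − Gly  | CA     | N, CA, C, CB              | + (L)        |
| Thr                | CB     | CA, CB, OG1, CG2          | + (3R)       |
| Ile                | CB     | CA, CB, CG1, CG2          | + (3S)       |
| purine nucleotides | C1′    | O4′, C1′, C2′, N9         | + (β-D)      |
| pyrimidine nucl.   | C1′    | O4′, C1′, C2′, N1         | + (β-D)      |
| ribonucleotides    | C2′    | C3′, C2′, C1′, O2′        | +            |
| all nucleotides    | C3′    | C4′, C3′, C2′, O3′        | +            |
| all nucleotides    | C4′    | C5′, C4′, C3′, O4′        | +            |

A negative improper therefore flags an unusual configuration. A flag is
*not* a verdict of error: D-amino acids occur in nature (bacterial cell
walls, non-ribosomal peptides), which is why detection and correction are
separate user-driven steps and nothing is ever auto-corrected.

### Torsion convention

All torsions follow the IUPAC convention (clockwise rotation of the far
bond positive when viewed from the second toward the third atom), returned
in (−180°, +180°] with the boundary mapped to +180 so ideal *trans* is a
single representable value. No published convention is assumed by
detection itself — only |ω′| and the calibrated improper sign enter the
verdicts, so any self-consistent convention would give identical flags;
the convention is nevertheless pinned by a brute-force rotation-oracle
test. Degenerate (collinear or coincident) inputs raise an explicit error
rather than returning 0; during a structure scan such sites become
unevaluable records instead of exceptions.

## Correction

Step one is a pure reflection: the carbonyl O through its C (or the amide
H through its N) for a peptide bond; the α (or equivalent) hydrogen
through the chiral atom for a center. Cα atoms are never moved, minimizing
structural impact. Which atom to move (O vs H) depends on the local
hydrogen-bond environment and is left to the user; H moves are impossible
in hydrogen-free crystallographic models and for Xaa-Pro bonds, where O is
the fallback. For chirality the hydrogen was chosen as the moved atom
because it is the smallest substituent; the heavy-atom inversion is then
completed by the restrained relaxation.

Step two, `regularize_local`, minimizes a harmonic bonded-term model over
the residues with any atom within a cutoff (default 8 Å) of the site;
atoms outside the mobile set are bit-identical in the output. The model
contains:

- **bonds**: k(r−r₀)², k = 300 kcal·mol⁻¹·Å⁻², r₀ from a standard
  peptide-geometry table (N-Cα 1.458, Cα-C 1.525, C-N 1.329, C=O 1.231 Å,
  side chains per residue);
- **angles**: k(θ−θ₀)², k = 80 kcal·mol⁻¹·rad⁻², θ₀ from the same table
  with a tetrahedral fallback, enumerated from the bond graph;
- **peptide planarity impropers**: k(Δ)², k = 40 kcal·mol⁻¹·rad⁻², on
  (Cα(n), N(n+1), C(n), O(n)) and (Cα(n+1), C(n), N(n+1), H(n+1)), both
  with reference 180°, which holds for *both* isomers — these terms
  enforce planarity without biasing cis against trans;
- **target restraints**: k(Δ)² with periodic wrapping of Δ into
  (−180°, 180°], k = 200 kcal·mol⁻¹·rad⁻² by default — ω reference 180°
  (or 0° for a bond kept cis), improper reference equal to the mirrored
  current value for an inversion.

Minimization is L-BFGS-B with analytic gradients (the torsion gradient was
validated against finite differences to ~1e-7), an iteration budget of
2000, and convergence declared at max gradient ≤ 0.1 kcal·mol⁻¹·Å⁻¹; on
non-convergence the best coordinates found are returned with a warning and
a `converged=False` flag. All constants are overridable and are this
package's own declared defaults. There are no nonbonded terms: the
regularizer is a stereochemistry-restoration tool operating near an
already-reasonable structure, not a force field, so clashes introduced by
a large conformational swing must be handled by the user's subsequent
equilibration.

Preserving restraints (`generate_restraints`) emit one ω dihedral per
evaluable bond (reference 180/0 by current isomer) and one improper per
evaluable center (reference = its current improper), with 0-based indices
into the serialized atom order. The extra-bonds text format round-trips
losslessly (floats are written in shortest-repr form). These files are for
relaxation phases where large forces act (flexible fitting, high-T
protocols) and should be removed before production equilibrium runs.

## Synthetic structures

`fixtures.build_peptide` constructs peptides atom-by-atom with the
natural-extension reference frame from ideal bond lengths/angles and
user-chosen φ/ψ/ω (defaults −57/−47/180: an α-helix; default sequence the
15-mer AAQAAAAQAAAAQAA with perturbation sites at Gln8 / bond 8-9).
Because placement is exact, built backbone dihedrals match the spec to
well under 1°, and the built structures are exact minima of the
regularizer's energy model — the angle table and the builder share their
reference values by construction. The carbonyl O is placed exactly anti to
the next N, so ω′ = ω − 180 holds exactly and a bond with a prescribed
|ω′| can be synthesized directly.

Supported residues: A, G, Q, T, I, P. Injections: `cis_bonds` (ω := 0 at
listed bonds) and `d_residues` (side-chain and α-H placements swapped
about the N-Cα-C plane, inverting the center without touching the
backbone). Hydrogens (amide H, α-H) are optional; termini are uncapped by
default with an acetyl/amide option. Gln's rotamer is an arbitrary
anti-anti choice (no test depends on it), and the proline ring is built
from fixed χ values and not exactly closed — its closure bond is excluded
from the bond-deviation checks.

What the generator does **not** emulate: thermal noise, nonbonded packing,
solvent, real side-chain rotamer distributions, experimental coordinate
error, or the header idiosyncrasies of deposited entries. Passing the
fixture battery therefore demonstrates the correctness of the geometry,
classification logic, correction contracts and header cross-validation —
not detection performance on noisy experimental coordinates, where the
wide 85° margin is what provides robustness.

The one-nucleotide fixture is a synthetic idealized adenosine (frozen
coordinates from a CIP-verified, MMFF-optimized small-molecule model); its
DNA variant simply drops O2′. It exists to exercise the sugar templates.

## Survey and header cross-validation

Only the first MODEL and, per residue, the first-encountered altLoc
identifier are read. Cis-bond detections are matched to CISPEP records on
the full residue identifiers (chain, number, insertion code) of both
partners: detections without a record are `unreported_cis`, records
without a detection `header_only_cis`. Chirality is compared at structure
level only (flags vs presence of CAVEAT or REMARK 500 chirality lines),
because CAVEAT is free-format and chirality errors are rarely itemized;
per-residue matching of REMARK 500 text is not attempted. Insertion-code
residues are carried through as part of residue identity.

Aggregation produces one row per experimental method seen plus an "All"
row; `residues_per_error` = Σ residues checked ÷ Σ errors rounded to
integer (absent at zero errors), percentages rounded to integer. Since
chirality errors and cis bonds have very different base rates, the
aggregator can total either kind separately or their sum (`kind=`). Both
the "all residues" and "evaluable residues" denominators are carried in
per-structure results (`residues_total`, `residues_checked`); aggregation
uses the evaluable count. Surveys are resumable through a JSON-lines cache
keyed by file checksum.

## Numerical choices and limitations

- Collinearity tolerance for torsions: cross-product norm < 1e-10 Å².
- Coordinates are PDB fixed-column; round trips are lossless to 0.001 Å.
  mmCIF is out of scope: every header record used for cross-validation
  (CISPEP, CAVEAT, REMARK 500, EXPDTA) is a PDB-format construct.
- Hydrogens are recognized by element column with an atom-name fallback
  (digits stripped, leading H/D).
- The regularizer's bonded templates cover the standard amino acids used
  by the builder plus caps; residues without a template contribute no
  internal terms and are left where they are.
- A correction that must rotate ω by ~180° moves the mobile region through
  a large swing; with bonded terms only there is no steric penalty along
  the path, which is what makes the local minimization reliable, but also
  why the result should be re-equilibrated with a proper force field.
- Problem sizes used in the test suite and acceptance script (15-residue
  fixtures, 50 mirror builds, 1000 oracle draws, 100 rigid motions) are
  the package's chosen verification set; all complete in seconds.
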