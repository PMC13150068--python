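# Methods

This note documents the model behind `spherevox`, the choices made where
the design was genuinely open, the synthetic data the tests run on, and
what the tests do and do not establish about real structures.

## Input model and merging

A protein enters as a paired PDB + TRIPOS MOL2 file describing the same
atoms in the same order. The PDB side contributes coordinates, chain ids,
residue names and author residue numbers; the MOL2 side contributes SYBYL
atom types (element + hybridization, e.g. `C.3`, `N.pl3`, `O.co2`) and the
covalent bond list with type codes `1/2/3/ar/am`. The merge pairs atoms
**ordinally** (i-th to i-th) and cross-checks coordinates at a configurable
tolerance, default 0.01 Å per axis; any disagreement, or an atom-count
mismatch, excludes the whole structure as inconsistently annotated. The
tolerance default is our choice: large enough to absorb format rounding
(PDB prints 3 decimals, MOL2 four), small enough that a genuinely shifted
atom cannot pass.

Element categories come from the SYBYL type (the substring before the first
`.`), restricted to the vocabulary {H, C, N, O, P, S}; when simplification
fails, the PDB element column is used as a fallback before giving up. Atoms
outside the six-element vocabulary (e.g. selenium, metals) are dropped
together with every bond touching them — the occupancy tensor has exactly
six atom-type channels, so such atoms have nowhere to live. Alternate
locations keep the first-listed conformer per atom name; HETATM records are
excluded by default (waters always), because the representation is defined
over protein residues. Hydrogens are used when present and never added; a
structure without explicit hydrogens simply leaves the H channel empty.

## Residue frames

Each residue's backbone N, Cα, C defines its frame: origin at the
unweighted centroid, x̂ = (Cα − N)/‖·‖, ẑ along (Cα − N) × (C − Cα),
ŷ = ẑ × x̂. Any fixed right-handed convention built from these three atoms
yields the same invariance properties; this one was chosen because it
degenerates only when the backbone is collinear (cross-product norm
< 1e-8), which raises a degenerate-frame error. Residues missing any of
N/Cα/C are skipped entirely — no environment, no bond row, no metadata
line — and logged; box indices stay consecutive over the residues actually
processed. The projection is a proper rigid map, so pairwise distances are
preserved exactly and two structures differing by a proper rigid motion
produce identical local coordinates. Reflections are *not* normalized
away: a mirrored structure produces different local coordinates, which is
intentional, as chirality is biochemically meaningful.

## Lattice, masking, occupancy

The lattice has half-width B (the sphere radius) and spacing s, with
n = 2B/s + 1 points per axis at −B, −B+s, …, +B. B and s must be
commensurate (2B/s integer within 1e-9); this puts a lattice point exactly
on the centroid and on ±B. Defaults are B = 16 Å, s = 1 Å (n = 33).

Masking: the bounding box max(|x|,|y|,|z|) ≤ B always applies; spherical
mode (default on) additionally keeps only ‖x‖ ≤ B. Both bounds are
inclusive. Atoms are snapped to the nearest lattice point,
index = ⌊(coord + B)/s + 1/2⌋ per axis — half-up, so a coordinate exactly
between two planes deterministically goes to the larger index. Occupancy is
binary: an atom sets bit (i, j, k, element, flag) where the flag is 0 for
the frame's own residue and 1 for neighbors; several same-element,
same-flag atoms in one voxel collapse to a single 1. A count mode
(`binary=False`) exists but defaults off. A voxel holding both a central
and a neighboring atom of the same element sets both flags — membership is
a factor axis, not a partition of voxels.

## Bond features

Per environment, bonds whose **both** endpoints survive the mask are
counted into the 5-vector (single, double, triple, aromatic, amide); MOL2
codes outside these five (`un`, `du`, `nc`, …) are parsed as `other` and
never counted. Counting over the masked atom set, rather than over the
whole molecule, makes the row a property of the local microenvironment and
makes the counts elementwise monotone in B on nested spheres; the
whole-molecule alternative would make every row identical. A bond with one
endpoint outside the sphere is not counted.

## Output contract

Per protein: `output_vox_atoms/<id>.npy` with shape (R, n, n, n, 6, 2),
`output_vox_bonds/<id>.npy` with shape (R, 5), and `metadata/<id>.txt`, a
tab-separated table (with header) of protein id, box index, author residue
index, residue label — all three row-aligned. The box index is a 0-based
ordinal over processed residues; it coincides with author numbering only
when numbering starts at 0 and nothing is skipped. NPY was chosen for
lossless, dependency-free round trips of integer tensors; writes are
deterministic, so re-running produces byte-identical files.

## Synthetic fixtures

The toy-peptide generator emits paired PDB/MOL2 text for short extended
chains with ideal bond lengths (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å,
C=O 1.23 Å) and known ground truth (atom table, residue order, bond
multiset). Five residue flavors cover the code paths: GLY (backbone only),
ALA (+Cβ), SER (+Oγ), CYS (+Sγ, exercising the S channel), PHE (a
two-carbon stub with an aromatic bond).

One construction detail matters for exact testing. Voxel equality under a
rigid motion is only reproducible when no atom sits so close to an
assignment boundary that coordinate rounding (3 decimals in PDB text) can
flip its voxel. The generator therefore builds the chain from a single
canonical backbone template repeated at an integer lattice offset between
consecutive residues: every residue frame is then an integer translation of
the same pose, so an atom's fractional coordinates on the default 1 Å
lattice are identical in every frame, and clearance only has to be enforced
once per atom. The template's N–Cα–C angle is solved (by bisection) so the
inter-residue peptide bond keeps exactly its ideal length given the integer
offset; carbonyl and side-chain positions are rejection-sampled around
ideal offsets, deterministically from the spec's seed, until each clears
the half-spacing boundaries by ≥ 0.05 Å. Corruption helpers inject single
targeted defects (shifted MOL2 atom, missing Cα, missing bond section, a
selenium atom) to exercise the documented exclusion paths, and a rigid
transform helper rewrites both texts under x → Rx + t, rejecting improper
rotations.

What the fixtures do **not** emulate: real backbone dihedral distributions,
rotamers, multiple chains or models, insertion codes, disorder, crystal
contacts, or converter quirks in real MOL2 files. Passing tests establish
the geometric and bookkeeping contracts of the pipeline, not robustness to
the full diversity of the PDB archive.

## Numerical choices

- Frame orthonormality enforced to 1e-9; collinearity threshold 1e-8 on
  the cross-product norm.
- Lattice commensurability tolerance 1e-9 on 2B/s; the error message
  suggests the nearest valid B.
- Mask bounds inclusive; assignment ties half-up. Ties are measure-zero on
  real data but must be deterministic.
- Rigid-motion invariance is exact (tensor equality) on the fixtures by
  the boundary-clearance construction above; on arbitrary structures,
  atoms arbitrarily close to a boundary can legitimately flip voxels under
  coordinate re-serialization.

## Problem sizes

Tests and the acceptance script run on 1–5 residue toy peptides, lattices
up to 65³, 10⁴-point discretization oracles, and 20-transform invariance
sweeps; the full suite completes in seconds on one core. These sizes fully
exercise every code path (the pipeline is linear in atoms × residues);
nothing about the contracts changes with protein size.

## Known limitations

- One conformer: only the first PDB model is read; altlocs beyond the
  first-listed are discarded.
- No mmCIF input and no PDB→MOL2 conversion; the MOL2 must be supplied
  with matching atom order.
- Binary occupancy discards multiplicity within a voxel at the default
  setting.
- The representation reduces, but does not eliminate, orientation
  dependence of learned models: frames are residue-aligned, not
  rotation-equivariant features.
- Bond counting is confined to the five named MOL2 types; exotic bond
  codes are ignored by design.
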