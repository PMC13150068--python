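# spherevox

Residue-centered spherical voxelization of protein structures.

Machine-learning models that read 3D protein structure need the structure
encoded as numbers. Most volumetric encoders build one global Cartesian
density grid per protein, which smooths away atom identity, is sensitive to
the protein's arbitrary orientation in the file, and gives no notion of
"this residue versus its surroundings". `spherevox` takes the opposite,
residue-centric view: it produces **one voxel map per residue**, expressed
in that residue's own backbone coordinate frame, with discrete chemical
channels rather than smoothed densities. The intended users are structural
bioinformaticians building residue-level predictors (secondary structure,
mutation effects, binding sites) with 3D CNNs or classical ML.

## The representation

For each residue with a complete backbone, the atoms N, Cα, C define a
local orthonormal frame: the origin is their centroid,

  o = (N + Cα + C) / 3,

the x-axis lies along N→Cα, the N→Cα→C plane is the xy-plane, and
z = x × y completes a right-handed system. Projecting every atom into this
frame removes the structure's global position and orientation (proper rigid
motions only — reflections are deliberately not normalized away, since they
change chirality).

A cubic lattice with half-width *B* (Å) and spacing *s* (Å) is centered on
the frame, with 2B/s + 1 points per axis spanning −B…+B. Atoms within the
sphere ‖x‖ ≤ B (or, with spherical masking off, within the bounding box
max(|x|,|y|,|z|) ≤ B) are snapped to the nearest lattice point, ties
rounding toward the larger index. Each atom sets a binary occupancy bit in
one of 6 atom-type channels — H, C, N, O, P, S, derived by simplifying the
MOL2 file's SYBYL types (C.3 → C, N.pl3 → N, O.co2 → O) — crossed with a
2-way membership flag: central residue vs. neighboring residues. Per
protein this yields an occupancy tensor of shape

  (R × n × n × n × 6 × 2),   n = 2B/s + 1,

for R processed residues. In parallel, covalent bonds from the MOL2 file
whose endpoints both survive the mask are counted by type into a per-residue
5-vector (single, double, triple, aromatic, amide), giving an (R × 5) bond
feature matrix.

Inputs are paired files per protein: a PDB file (coordinates, chains,
residue identities) and a TRIPOS MOL2 file with matching atom order
(SYBYL atom types, covalent bonds). The two are merged ordinally with a
coordinate cross-check; structures whose annotations disagree are excluded.

## Worked example

```python
from pathlib import Path
from spherevox.fixtures import ToySpec, make_toy_peptide
from spherevox.structure_io import load_structure
from spherevox.voxelizer import voxelize_protein
from spherevox.outputs import wrap_results, write_all

# a synthetic ALA-GLY-SER tripeptide with known geometry and bonds
pdb_text, mol2_text, _ = make_toy_peptide(ToySpec(n_residues=3))
Path("toy_peptide.pdb").write_text(pdb_text)
Path("toy_peptide.mol2").write_text(mol2_text)

structure = load_structure("toy_peptide.pdb", "toy_peptide.mol2")
vox = voxelize_protein(structure, B=16.0, s=1.0, use_spheres=True)
wrapper = wrap_results(vox)

print("residue environments:", len(wrapper))
print("occupancy tensor:", wrapper.occupancy.shape)
print("bond matrix:")
print(wrapper.bonds)
env = wrapper.by_box_index(0)
print("central-residue voxels in sphere 0:", int(env.occupancy[..., 0].sum()))
print("neighbor voxels in sphere 0:", int(env.occupancy[..., 1].sum()))
write_all(vox, "out")
```

prints

```
residue environments: 3
occupancy tensor: (3, 33, 33, 33, 6, 2)
bond matrix:
[[9 3 0 0 2]
 [9 3 0 0 2]
 [9 3 0 0 2]]
central-residue voxels in sphere 0: 5
neighbor voxels in sphere 0: 10
```

Three residues give three environments on the default 33-point lattice
(B = 16 Å, s = 1 Å). At this radius every sphere contains the whole
tripeptide, so all three bond rows agree: 9 single bonds, 3 C=O double
bonds, 2 peptide (amide) bonds, no triple or aromatic bonds. Sphere 0 is
centered on the alanine: its 5 central voxels hold the residue's own
N, Cα, C, O and Cβ atoms; the 10 neighbor voxels hold the other two
residues' atoms. `write_all` lays the results out on disk as

```
out/output_vox_atoms/toy_peptide.npy   # (3, 33, 33, 33, 6, 2) uint8
out/output_vox_bonds/toy_peptide.npy   # (3, 5) int64
out/metadata/toy_peptide.txt           # TSV: protein_id, box_index,
                                       #      residue_index, residue_label
```

The same pipeline is available from the shell:

```
spherevox voxelize --pdb toy_peptide.pdb --mol2 toy_peptide.mol2 \
    --box_size 16 --spacing 1 --use_spheres 1 --outdir out
```

Batch mode (`--input_dir`) pairs files by shared basename, skips structures
with inconsistent annotations, and writes a `manifest.tsv` of successes and
skips.

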