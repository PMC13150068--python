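"""Lattice construction, masking, voxel assignment, and bond counting."""

import numpy as np
import pytest

from spherevox.frames import LocalAtomSet, backbone_coords, residue_frame
from spherevox.structure_io import BondRecord
from spherevox.voxelizer import (
    BOND_COLUMNS,
    ELEMENT_CHANNELS,
    EmptyOutputError,
    LatticeConfigError,
    assign_voxel,
    box_mask,
    build_environment,
    build_lattice,
    count_bonds,
    sphere_mask,
    voxelize_protein,
)


def cloud(coords, central=None):
    """LocalAtomSet from bare coordinates (all carbon, sequential ids)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    central = np.zeros(n, dtype=bool) if central is None else np.asarray(central)
    return LocalAtomSet(
        local_coords=coords,
        element_category=np.array(["C"] * n),
        atom_ids=np.arange(1, n + 1),
        is_central=central,
        residue_key=("A", 1, "ALA"),
    )


class TestBuildLattice:
    @pytest.mark.parametrize(
        "B,s,n", [(16.0, 1.0, 33), (1.0, 1.0, 3), (4.0, 0.5, 17), (8.0, 2.0, 9)]
    )
    def test_axis_count_and_span(self, B, s, n):
        lattice = build_lattice(B, s)
        assert lattice.n_per_axis == n
        assert lattice.axis_coords[0] == pytest.approx(-B, abs=1e-9)
        assert lattice.axis_coords[-1] == pytest.approx(B, abs=1e-9)
        np.testing.assert_allclose(np.diff(lattice.axis_coords), s, atol=1e-9)

    @pytest.mark.parametrize("B,s", [(1.0, 0.3), (16.0, 0.7), (-1.0, 1.0), (1.0, 0.0)])
    def test_non_commensurate_or_invalid_rejected(self, B, s):
        with pytest.raises(LatticeConfigError):
            build_lattice(B, s)


class TestMasks:
    def test_sphere_boundary_inclusive(self):
        B = 4.0
        atoms = cloud([[0, 0, 0], [B, 0, 0], [B + 1e-6, 0, 0]])
        kept = sphere_mask(atoms, B)
        assert list(kept.atom_ids) == [1, 2]

    def test_box_keeps_corner_that_sphere_drops(self):
        B = 4.0
        corner = cloud([[B, B, B]])
        assert len(box_mask(corner, B)) == 1
        assert len(sphere_mask(corner, B)) == 0

    def test_box_boundary(self):
        B = 4.0
        atoms = cloud([[0, 0, B], [0, 0, B + 1e-6]])
        assert list(box_mask(atoms, B).atom_ids) == [1]

    def test_masks_match_brute_force_filters(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-12, 12, size=(500, 3))
        atoms = cloud(coords)
        B = 8.0
        sphere_ids = set(sphere_mask(atoms, B).atom_ids)
        box_ids = set(box_mask(atoms, B).atom_ids)
        # independent oracle: per-atom norm filters
        expected_sphere = {
            i + 1 for i, c in enumerate(coords) if np.sqrt((c ** 2).sum()) <= B
        }
        expected_box = {i + 1 for i, c in enumerate(coords) if np.abs(c).max() <= B}
        assert sphere_ids == expected_sphere
        assert box_ids == expected_box
        assert sphere_ids <= box_ids


class TestAssignVoxel:
    def test_center_of_default_lattice(self):
        lattice = build_lattice(16.0, 1.0)
        assert assign_voxel((0.0, 0.0, 0.0), lattice) == (16, 16, 16)
        assert assign_voxel((0.4, -0.4, 0.0), lattice) == (16, 16, 16)

    def test_half_spacing_tie_goes_to_larger_index(self):
        lattice = build_lattice(2.0, 1.0)
        assert assign_voxel((0.5, -0.5, 1.5), lattice) == (3, 2, 4)

    def test_matches_exhaustive_nearest_point_search(self):
        lattice = build_lattice(4.0, 1.0)
        rng = np.random.default_rng(5)
        coords = rng.uniform(-4, 4, size=(10_000, 3))
        axis = lattice.axis_coords
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
        for c in coords[:: 25]:  # exhaustive 3-D check on a subsample
            d = np.linalg.norm(grid - c, axis=1)
            best = grid[np.argmin(d)]
            expected = tuple(int(round((v + 4.0) / 1.0)) for v in best)
            assert assign_voxel(c, lattice) == expected
        # full 10^4 check against the separable per-axis oracle
        for c in coords:
            expected = tuple(int(np.argmin(np.abs(axis - v))) for v in c)
            assert assign_voxel(c, lattice) == expected


class TestBuildEnvironment:
    def test_single_central_carbon_at_centroid(self, tripeptide_structure):
        key = tripeptide_structure.residue_order[0]
        frame = residue_frame(*backbone_coords(tripeptide_structure, key), residue_key=key)
        lattice = build_lattice(4.0, 1.0)
        env = build_environment(tripeptide_structure, frame, lattice, use_spheres=True)
        occ = env.occupancy
        assert occ.shape == (9, 9, 9, 6, 2)
        assert set(np.unique(occ)) <= {0, 1}
        # every retained atom is inside the sphere
        ids = set(env.retained_atom_ids)
        by_id = {a.atom_id: np.asarray(a.coords) for a in tripeptide_structure.atoms}
        for atom_id in ids:
            assert np.linalg.norm(frame.to_local(by_id[atom_id])) <= 4.0 + 1e-9

    def test_occupied_count_matches_per_atom_enumeration(self, tripeptide_structure):
        key = tripeptide_structure.residue_order[1]
        frame = residue_frame(*backbone_coords(tripeptide_structure, key), residue_key=key)
        lattice = build_lattice(8.0, 1.0)
        env = build_environment(tripeptide_structure, frame, lattice, use_spheres=True)
        nonzero = int(env.occupancy.sum())
        assert nonzero <= len(env.retained_atom_ids)
        # independent enumeration: distinct (voxel, element, flag) triples
        triples = set()
        key_atoms = {a.atom_id: a for a in tripeptide_structure.atoms}
        for atom_id in env.retained_atom_ids:
            a = key_atoms[atom_id]
            idx = assign_voxel(frame.to_local(np.asarray(a.coords)), lattice)
            triples.add((idx, a.element_category, a.residue_key == key))
        assert nonzero == len(triples)

    def test_central_channels_hold_exactly_central_atoms(self, tripeptide_structure):
        key = tripeptide_structure.residue_order[1]
        frame = residue_frame(*backbone_coords(tripeptide_structure, key), residue_key=key)
        lattice = build_lattice(16.0, 1.0)
        env = build_environment(tripeptide_structure, frame, lattice, use_spheres=True)
        n_central_voxels = int(env.occupancy[..., 0].sum())
        central_atoms = [
            a for a in tripeptide_structure.atoms
            if a.residue_key == key and a.atom_id in set(env.retained_atom_ids)
        ]
        assert n_central_voxels == len(central_atoms)  # no two share a voxel here


class TestCountBonds:
    BONDS = [
        BondRecord(1, 2, "single"),
        BondRecord(2, 3, "single"),
        BondRecord(3, 4, "amide"),
        BondRecord(4, 5, "double"),
        BondRecord(5, 6, "other"),
    ]

    def test_empty_environment(self):
        assert count_bonds([], self.BONDS).counts == (0, 0, 0, 0, 0)

    def test_direct_enumeration(self):
        row = count_bonds([1, 2, 3, 4], self.BONDS)
        assert row.counts == (2, 0, 0, 0, 1)

    def test_boundary_straddling_bond_not_counted(self):
        full = count_bonds([1, 2, 3, 4, 5], self.BONDS).counts
        without_endpoint = count_bonds([1, 2, 3, 4], self.BONDS).counts
        assert sum(full) - sum(without_endpoint) == 1

    def test_other_coded_bonds_never_counted(self):
        assert count_bonds([5, 6], self.BONDS).counts == (0, 0, 0, 0, 0)


class TestVoxelizeProtein:
    def test_tensor_shapes(self, tripeptide_structure):
        vox = voxelize_protein(tripeptide_structure, B=4.0, s=1.0)
        assert vox.occupancy_tensor().shape == (3, 9, 9, 9, 6, 2)
        assert vox.bond_tensor().shape == (3, 5)
        assert len(ELEMENT_CHANNELS) == 6 and len(BOND_COLUMNS) == 5

    def test_missing_backbone_residue_skipped(self, tripeptide, write_pair):
        from spherevox.fixtures import corrupt
        from spherevox.structure_io import load_structure

        pdb_text, mol2_text, _ = tripeptide
        paths = write_pair(*corrupt(pdb_text, mol2_text, "drop_backbone_atom"))
        vox = voxelize_protein(load_structure(*paths), B=4.0, s=1.0)
        assert len(vox.environments) == 2
        assert [rec["residue_index"] for rec in vox.metadata] == [1, 3]
        assert [rec["box_index"] for rec in vox.metadata] == [0, 1]
        assert vox.skipped[0][0][1] == 2

    def test_determinism(self, tripeptide_structure):
        a = voxelize_protein(tripeptide_structure, B=4.0, s=1.0)
        b = voxelize_protein(tripeptide_structure, B=4.0, s=1.0)
        assert np.array_equal(a.occupancy_tensor(), b.occupancy_tensor())
        assert np.array_equal(a.bond_tensor(), b.bond_tensor())
        assert a.metadata == b.metadata

    def test_bond_sum_equals_retained_five_type_bonds(self, tripeptide_structure):
        vox = voxelize_protein(tripeptide_structure, B=6.0, s=1.0)
        for env, row in zip(vox.environments, vox.bond_rows):
            retained = set(env.retained_atom_ids)
            expected = sum(
                1 for b in tripeptide_structure.bonds
                if b.bond_code != "other" and b.atom_a in retained and b.atom_b in retained
            )
            assert sum(row.counts) == expected

    def test_bond_counts_monotone_in_radius(self, tripeptide_structure):
        radii = [2.0, 3.0, 4.0, 6.0, 8.0, 16.0]
        tensors = [
            voxelize_protein(tripeptide_structure, B=B, s=1.0).bond_tensor()
            for B in radii
        ]
        for smaller, larger in zip(tensors, tensors[1:]):
            assert np.all(smaller <= larger)

    def test_large_box_covers_whole_molecule(self, tripeptide_structure):
        vox = voxelize_protein(tripeptide_structure, B=32.0, s=1.0)
        whole = {"single": 0, "double": 0, "triple": 0, "aromatic": 0, "amide": 0}
        for b in tripeptide_structure.bonds:
            if b.bond_code in whole:
                whole[b.bond_code] += 1
        per_residue = vox.bond_tensor()
        assert np.all(per_residue == per_residue[0])  # every sphere sees all bonds
        assert tuple(per_residue[0]) == tuple(whole[c] for c in BOND_COLUMNS)

    def test_no_processable_residue_raises(self, tripeptide, write_pair):
        from spherevox.fixtures import ToySpec, corrupt, make_toy_peptide
        from spherevox.structure_io import load_structure

        pdb_text, mol2_text, _ = make_toy_peptide(ToySpec(n_residues=1, residue_names=["GLY"]))
        paths = write_pair(*corrupt(pdb_text, mol2_text, "drop_backbone_atom"))
        with pytest.raises(EmptyOutputError):
            voxelize_protein(load_structure(*paths), B=4.0, s=1.0)

    def test_end_to_end_rigid_motion_invariance(self, tripeptide, write_pair):
        import numpy as np
        from conftest import random_proper_rotation
        from spherevox.fixtures import rigid_transform
        from spherevox.structure_io import load_structure

        pdb_text, mol2_text, _ = tripeptide
        reference = voxelize_protein(
            load_structure(*write_pair(pdb_text, mol2_text, "ref")), B=16.0, s=1.0
        )
        rng = np.random.default_rng(17)
        for k in range(20):
            R = random_proper_rotation(rng)
            t = rng.uniform(-30, 30, size=3)
            moved_paths = write_pair(*rigid_transform(pdb_text, mol2_text, R, t), f"mv{k}")
            moved = voxelize_protein(load_structure(*moved_paths), B=16.0, s=1.0)
            assert np.array_equal(
                reference.occupancy_tensor(), moved.occupancy_tensor()
            )
            assert np.array_equal(reference.bond_tensor(), moved.bond_tensor())
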