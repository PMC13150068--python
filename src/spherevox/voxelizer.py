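"""Voxel discretization of residue microenvironments.

A cubic lattice of half-width B (Å) and spacing s (Å) is centered on each
residue frame; 2B/s must be an integer so a lattice point falls exactly on
the centroid and on ±B.  Atoms are masked (sphere ‖x‖ ≤ B when spherical
mode is on; the bounding box always applies), snapped to the nearest
lattice point with half-up tie-breaking, and recorded as binary occupancy
in 6 atom-type channels (H, C, N, O, P, S) × 2 membership flags
(central residue, neighboring residues).  Covalent bonds whose endpoints
both survive the mask are counted by type into a 5-vector
(single, double, triple, aromatic, amide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .frames import (
    DegenerateFrameError,
    LocalAtomSet,
    backbone_coords,
    project_atoms,
    residue_frame,
)
from .structure_io import AnnotatedStructure, BondRecord

__all__ = [
    "LatticeSpec",
    "SphereEnvironment",
    "BondFeatureRow",
    "ProteinVoxelization",
    "build_lattice",
    "sphere_mask",
    "box_mask",
    "assign_voxel",
    "build_environment",
    "count_bonds",
    "voxelize_protein",
    "LatticeConfigError",
    "EmptyOutputError",
    "ELEMENT_CHANNELS",
    "BOND_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Fixed channel order of the atom-type axis.
ELEMENT_CHANNELS = ("H", "C", "N", "O", "P", "S")
_CHANNEL_INDEX = {e: i for i, e in enumerate(ELEMENT_CHANNELS)}

#: Fixed column order of the bond feature matrix.
BOND_COLUMNS = ("single", "double", "triple", "aromatic", "amide")
_BOND_INDEX = {b: i for i, b in enumerate(BOND_COLUMNS)}

#: Membership flag axis: index 0 = central residue, 1 = neighboring residues.
FLAG_CENTRAL, FLAG_NEIGHBOR = 0, 1


class LatticeConfigError(ValueError):
    """Box size and spacing are not commensurate."""


class EmptyOutputError(ValueError):
    """No residue of the structure could be voxelized."""


@dataclass(frozen=True)
class LatticeSpec:
    """A cubic lattice spanning −B…+B per axis at uniform spacing s."""

    box_size_B: float
    spacing_s: float
    n_per_axis: int
    axis_coords: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.n_per_axis
        return (n, n, n)


@dataclass
class SphereEnvironment:
    """One residue's voxelized microenvironment."""

    box_index: int
    residue_key: tuple[str, int, str]
    occupancy: np.ndarray  # (n, n, n, 6, 2) uint8, binary
    retained_atom_ids: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class BondFeatureRow:
    """Counts of (single, double, triple, aromatic, amide) bonds."""

    counts: tuple[int, int, int, int, int]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass
class ProteinVoxelization:
    """Per-protein bundle of environments, bond rows, and metadata."""

    protein_id: str
    lattice: LatticeSpec
    environments: list[SphereEnvironment]
    bond_rows: list[BondFeatureRow]
    metadata: list[dict]
    skipped: list[tuple[tuple[str, int, str], str]] = field(default_factory=list)

    def occupancy_tensor(self) -> np.ndarray:
        """Stack environments into an array of shape (R, n, n, n, 6, 2)."""
        return np.stack([env.occupancy for env in self.environments])

    def bond_tensor(self) -> np.ndarray:
        """Stack bond rows into an array of shape (R, 5)."""
        return np.stack([row.as_array() for row in self.bond_rows])


def build_lattice(B: float, s: float) -> LatticeSpec:
    """Construct the lattice for half-width ``B`` and spacing ``s`` (Å).

    n_per_axis = 2B/s + 1 with axis values −B, −B+s, …, +B; raises
    :class:`LatticeConfigError` when 2B/s is not an integer (suggesting the
    nearest commensurate B).
    """
    if B <= 0 or s <= 0:
        raise LatticeConfigError("box size and spacing must be positive")
    ratio = 2.0 * B / s
    n_intervals = round(ratio)
    if abs(ratio - n_intervals) > 1e-9 or n_intervals < 1:
        suggestion = max(1, n_intervals) * s / 2.0
        raise LatticeConfigError(
            f"2B/s = {ratio:.6g} is not an integer; nearest valid box size "
            f"for spacing {s} is B = {suggestion:g} Å"
        )
    n = n_intervals + 1
    axis = -B + s * np.arange(n)
    return LatticeSpec(box_size_B=float(B), spacing_s=float(s), n_per_axis=n, axis_coords=axis)


def sphere_mask(atoms: LocalAtomSet, B: float) -> LocalAtomSet:
    """Keep atoms with Euclidean norm ‖x‖ ≤ B (boundary inclusive)."""
    keep = np.linalg.norm(atoms.local_coords, axis=1) <= B
    return atoms.subset(keep)


def box_mask(atoms: LocalAtomSet, B: float) -> LocalAtomSet:
    """Keep atoms inside the bounding box max(|x|,|y|,|z|) ≤ B."""
    if len(atoms) == 0:
        return atoms.subset(np.zeros(0, dtype=bool))
    keep = np.max(np.abs(atoms.local_coords), axis=1) <= B
    return atoms.subset(keep)


def assign_voxel(local_coord, lattice: LatticeSpec) -> tuple[int, int, int]:
    """Index triple of the lattice point nearest to ``local_coord``.

    index_k = ⌊(coord_k + B)/s + 1/2⌋ — nearest integer with half-up
    tie-breaking, so a coordinate exactly midway between two lattice planes
    goes to the larger index.  Inputs are assumed pre-masked, which keeps
    every index within [0, n_per_axis − 1].
    """
    idx = _assign_voxels(np.asarray(local_coord, dtype=float)[None, :], lattice)[0]
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def _assign_voxels(coords: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
    idx = np.floor((coords + lattice.box_size_B) / lattice.spacing_s + 0.5).astype(int)
    return np.clip(idx, 0, lattice.n_per_axis - 1)


def build_environment(
    structure: AnnotatedStructure,
    frame,
    lattice: LatticeSpec,
    use_spheres: bool = True,
    *,
    box_index: int = 0,
    binary: bool = True,
) -> SphereEnvironment:
    """Voxelize one residue's local atom set.

    Atoms are projected into ``frame``, masked (box always; sphere when
    ``use_spheres``), and snapped to voxels.  Occupancy is binary by
    default: multiple same-element/same-flag atoms in one voxel collapse
    to 1 (``binary=False`` counts them instead).
    """
    atoms = project_atoms(structure, frame)
    atoms = box_mask(atoms, lattice.box_size_B)
    if use_spheres:
        atoms = sphere_mask(atoms, lattice.box_size_B)

    n = lattice.n_per_axis
    dtype = np.uint8 if binary else np.int64
    occupancy = np.zeros((n, n, n, len(ELEMENT_CHANNELS), 2), dtype=dtype)
    if len(atoms):
        indices = _assign_voxels(atoms.local_coords, lattice)
        channels = np.array([_CHANNEL_INDEX[e] for e in atoms.element_category])
        flags = np.where(atoms.is_central, FLAG_CENTRAL, FLAG_NEIGHBOR)
        if binary:
            occupancy[indices[:, 0], indices[:, 1], indices[:, 2], channels, flags] = 1
        else:
            np.add.at(
                occupancy,
                (indices[:, 0], indices[:, 1], indices[:, 2], channels, flags),
                1,
            )
    return SphereEnvironment(
        box_index=box_index,
        residue_key=frame.residue_key,
        occupancy=occupancy,
        retained_atom_ids=[int(i) for i in atoms.atom_ids],
    )


def count_bonds(retained_atom_ids, bonds: list[BondRecord]) -> BondFeatureRow:
    """Count bonds with both endpoints retained, binned by bond type.

    Bonds coded ``other`` are never counted; the result is the 5-vector
    (single, double, triple, aromatic, amide).
    """
    retained = set(retained_atom_ids)
    counts = [0, 0, 0, 0, 0]
    for bond in bonds:
        if bond.bond_code == "other":
            continue
        if bond.atom_a in retained and bond.atom_b in retained:
            counts[_BOND_INDEX[bond.bond_code]] += 1
    return BondFeatureRow(counts=tuple(counts))


def voxelize_protein(
    structure: AnnotatedStructure,
    B: float = 16.0,
    s: float = 1.0,
    use_spheres: bool = True,
    *,
    binary: bool = True,
) -> ProteinVoxelization:
    """Voxelize every residue of a structure.

    One environment, bond row and metadata record is emitted per residue
    with a complete, non-degenerate N/Cα/C backbone, in residue order.
    Residues with missing backbone atoms are skipped and logged; the
    lattice is built once and reused across residues.
    """
    lattice = build_lattice(B, s)
    environments: list[SphereEnvironment] = []
    bond_rows: list[BondFeatureRow] = []
    metadata: list[dict] = []
    skipped: list[tuple[tuple[str, int, str], str]] = []

    box_index = 0
    for key in structure.residue_order:
        backbone = backbone_coords(structure, key)
        if backbone is None:
            skipped.append((key, "incomplete backbone"))
            logger.warning("skipping residue %s: incomplete backbone", key)
            continue
        try:
            frame = residue_frame(*backbone, residue_key=key)
        except DegenerateFrameError as exc:
            skipped.append((key, str(exc)))
            logger.warning("skipping residue %s: degenerate frame", key)
            continue
        env = build_environment(
            structure, frame, lattice, use_spheres, box_index=box_index, binary=binary
        )
        environments.append(env)
        bond_rows.append(count_bonds(env.retained_atom_ids, structure.bonds))
        chain_id, residue_index, residue_name = key
        metadata.append(
            {
                "protein_id": structure.protein_id,
                "box_index": box_index,
                "residue_index": residue_index,
                "residue_label": residue_name.upper(),
                "chain_id": chain_id,
            }
        )
        box_index += 1

    if not environments:
        raise EmptyOutputError(
            f"{structure.protein_id}: no residue with a complete backbone"
        )
    return ProteinVoxelization(
        protein_id=structure.protein_id,
        lattice=lattice,
        environments=environments,
        bond_rows=bond_rows,
        metadata=metadata,
        skipped=skipped,
    )
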