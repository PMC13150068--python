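"""Serialization of voxelization results.

Per protein, three files are written under fixed subdirectories:

* ``output_vox_atoms/<protein_id>.npy`` — the occupancy tensor, shape
  (R, n, n, n, 6, 2), binary, channel order (H, C, N, O, P, S) ×
  (central, neighbor);
* ``output_vox_bonds/<protein_id>.npy`` — the bond feature matrix, shape
  (R, 5), integer counts ordered (single, double, triple, aromatic, amide);
* ``metadata/<protein_id>.txt`` — a tab-separated table with one row per
  environment (protein id, box index, residue index, residue label),
  parallel to the array row order.

:func:`wrap_results` exposes the same bundle in memory, indexable by box
index or residue key.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .voxelizer import ProteinVoxelization, SphereEnvironment, EmptyOutputError

__all__ = [
    "MetadataRecord",
    "DataWrapper",
    "write_occupancy",
    "write_bonds",
    "write_metadata",
    "write_all",
    "wrap_results",
]

ATOMS_DIR = "output_vox_atoms"
BONDS_DIR = "output_vox_bonds"
METADATA_DIR = "metadata"

_METADATA_HEADER = ("protein_id", "box_index", "residue_index", "residue_label")


@dataclass(frozen=True)
class MetadataRecord:
    protein_id: str
    box_index: int
    residue_index: int
    residue_label: str


def _require_environments(voxelization: ProteinVoxelization) -> None:
    if not voxelization.environments:
        raise EmptyOutputError("voxelization holds no environments; nothing to write")


def write_occupancy(voxelization: ProteinVoxelization, out_dir: str | os.PathLike) -> Path:
    """Write the (R, n, n, n, 6, 2) occupancy tensor as an .npy file."""
    _require_environments(voxelization)
    target = Path(out_dir) / ATOMS_DIR
    target.mkdir(parents=True, exist_ok=True)
    path = target / f"{voxelization.protein_id}.npy"
    np.save(path, voxelization.occupancy_tensor())
    return path


def write_bonds(voxelization: ProteinVoxelization, out_dir: str | os.PathLike) -> Path:
    """Write the (R, 5) bond count matrix as an .npy file."""
    _require_environments(voxelization)
    target = Path(out_dir) / BONDS_DIR
    target.mkdir(parents=True, exist_ok=True)
    path = target / f"{voxelization.protein_id}.npy"
    np.save(path, voxelization.bond_tensor())
    return path


def write_metadata(voxelization: ProteinVoxelization, out_dir: str | os.PathLike) -> Path:
    """Write the per-environment metadata table (TSV with header)."""
    _require_environments(voxelization)
    target = Path(out_dir) / METADATA_DIR
    target.mkdir(parents=True, exist_ok=True)
    path = target / f"{voxelization.protein_id}.txt"
    lines = ["\t".join(_METADATA_HEADER)]
    for rec in voxelization.metadata:
        lines.append(
            "\t".join(
                str(rec[field]) for field in _METADATA_HEADER
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_all(voxelization: ProteinVoxelization, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write occupancy, bonds and metadata; return the three paths."""
    return {
        "occupancy": write_occupancy(voxelization, out_dir),
        "bonds": write_bonds(voxelization, out_dir),
        "metadata": write_metadata(voxelization, out_dir),
    }


def read_metadata(path: str | os.PathLike) -> list[MetadataRecord]:
    """Read a metadata TSV back into records."""
    lines = Path(path).read_text().splitlines()
    records = []
    for line in lines[1:]:
        pid, box_index, residue_index, label = line.split("\t")[:4]
        records.append(
            MetadataRecord(
                protein_id=pid,
                box_index=int(box_index),
                residue_index=int(residue_index),
                residue_label=label,
            )
        )
    return records


class DataWrapper:
    """In-memory view of a voxelization, indexable by box index or residue key.

    Exposes the stacked occupancy tensor, bond matrix, metadata records,
    lattice axis coordinates and per-environment retained-atom id lists.
    """

    def __init__(self, voxelization: ProteinVoxelization):
        self._vox = voxelization
        self.protein_id = voxelization.protein_id
        self.occupancy = voxelization.occupancy_tensor()
        self.bonds = voxelization.bond_tensor()
        self.axis_coords = voxelization.lattice.axis_coords
        self.metadata = [
            MetadataRecord(
                protein_id=rec["protein_id"],
                box_index=rec["box_index"],
                residue_index=rec["residue_index"],
                residue_label=rec["residue_label"],
            )
            for rec in voxelization.metadata
        ]
        self.retained_atom_ids = [
            env.retained_atom_ids for env in voxelization.environments
        ]
        self._by_key = {
            env.residue_key: env.box_index for env in voxelization.environments
        }

    def __len__(self) -> int:
        return len(self._vox.environments)

    def __iter__(self):
        return iter(self._vox.environments)

    def by_box_index(self, box_index: int) -> SphereEnvironment:
        if not 0 <= box_index < len(self):
            raise KeyError(f"box index {box_index} out of range (R = {len(self)})")
        return self._vox.environments[box_index]

    def by_residue_key(self, key: tuple[str, int, str]) -> SphereEnvironment:
        if key not in self._by_key:
            raise KeyError(f"no environment for residue {key}")
        return self._vox.environments[self._by_key[key]]


def wrap_results(voxelization: ProteinVoxelization) -> DataWrapper:
    """Wrap a voxelization into a :class:`DataWrapper` view."""
    return DataWrapper(voxelization)
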