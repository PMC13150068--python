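"""Residue-centered backbone coordinate frames.

Each residue's backbone atoms N, Cα, C define a local orthonormal frame:
the origin is their centroid and the axes follow a right-handed
Gram–Schmidt convention on the N→Cα and Cα→C directions (x̂ along N→Cα,
the N→Cα→C plane as the local xy-plane, ẑ normal to it).  Projecting all
atoms into this frame removes the structure's global position and
orientation, so microenvironments from different proteins or conformers
can be compared directly.  The normalization covers proper rigid motions
only; reflections change the handedness and are deliberately not removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AnnotatedStructure

__all__ = [
    "ResidueFrame",
    "LocalAtomSet",
    "residue_frame",
    "project_atoms",
    "DegenerateFrameError",
]

_COLLINEAR_EPS = 1e-8

#: Backbone atom names required to define a frame.
BACKBONE_ATOMS = ("N", "CA", "C")


class DegenerateFrameError(ValueError):
    """Backbone atoms are collinear or coincident; no frame exists."""


@dataclass(frozen=True)
class ResidueFrame:
    """Origin (backbone centroid, Å) and global→local rotation for a residue."""

    origin: np.ndarray
    rotation: np.ndarray
    residue_key: tuple[str, int, str]

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        """Map global coordinates (..., 3) into this frame."""
        return (np.asarray(coords, dtype=float) - self.origin) @ self.rotation.T


@dataclass
class LocalAtomSet:
    """Atoms expressed in one residue's local frame.

    Parallel arrays: ``local_coords`` (N, 3) Å, ``element_category`` (N,)
    strings, ``atom_ids`` (N,) MOL2 ids, ``is_central`` (N,) booleans that
    are true exactly for atoms of the frame-defining residue.
    """

    local_coords: np.ndarray
    element_category: np.ndarray
    atom_ids: np.ndarray
    is_central: np.ndarray
    residue_key: tuple[str, int, str]

    def __len__(self) -> int:
        return len(self.atom_ids)

    def subset(self, keep: np.ndarray) -> "LocalAtomSet":
        return LocalAtomSet(
            local_coords=self.local_coords[keep],
            element_category=self.element_category[keep],
            atom_ids=self.atom_ids[keep],
            is_central=self.is_central[keep],
            residue_key=self.residue_key,
        )


def residue_frame(
    n_coord,
    ca_coord,
    c_coord,
    residue_key: tuple[str, int, str],
) -> ResidueFrame:
    """Build the backbone frame from the N, Cα and C positions.

    origin = (N + Cα + C) / 3.  Axes: x̂ = (Cα − N)/‖·‖, ẑ normal to the
    N→Cα→C plane via (Cα − N) × (C − Cα), ŷ = ẑ × x̂.  The rotation matrix
    rows are (x̂, ŷ, ẑ), so it maps global into local coordinates.
    """
    n = np.asarray(n_coord, dtype=float)
    ca = np.asarray(ca_coord, dtype=float)
    c = np.asarray(c_coord, dtype=float)
    if not (np.all(np.isfinite(n)) and np.all(np.isfinite(ca)) and np.all(np.isfinite(c))):
        raise ValueError("backbone coordinates must be finite")

    u = ca - n
    v = c - ca
    normal = np.cross(u, v)
    nu = np.linalg.norm(u)
    nn = np.linalg.norm(normal)
    if nu < _COLLINEAR_EPS or nn < _COLLINEAR_EPS:
        raise DegenerateFrameError(
            f"backbone atoms of residue {residue_key} are collinear or coincident"
        )
    x_hat = u / nu
    z_hat = normal / nn
    y_hat = np.cross(z_hat, x_hat)

    rotation = np.vstack([x_hat, y_hat, z_hat])
    origin = (n + ca + c) / 3.0
    return ResidueFrame(origin=origin, rotation=rotation, residue_key=residue_key)


def project_atoms(structure: AnnotatedStructure, frame: ResidueFrame) -> LocalAtomSet:
    """Express every retained atom of ``structure`` in ``frame``.

    local = R · (global − origin).  ``is_central`` marks atoms whose
    residue key equals the frame's.  The atom count is preserved; masking
    happens later in the voxelizer.
    """
    coords = structure.coords_array()
    local = frame.to_local(coords)
    elements = np.array([a.element_category for a in structure.atoms])
    atom_ids = np.array([a.atom_id for a in structure.atoms], dtype=int)
    central = np.array(
        [a.residue_key == frame.residue_key for a in structure.atoms], dtype=bool
    )
    return LocalAtomSet(
        local_coords=local,
        element_category=elements,
        atom_ids=atom_ids,
        is_central=central,
        residue_key=frame.residue_key,
    )


def backbone_coords(
    structure: AnnotatedStructure, key: tuple[str, int, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Return (N, Cα, C) coordinates for a residue, or None if incomplete."""
    found: dict[str, np.ndarray] = {}
    for atom in structure.atoms:
        if atom.residue_key == key and atom.atom_name in BACKBONE_ATOMS:
            found.setdefault(atom.atom_name, np.asarray(atom.coords, dtype=float))
    if all(name in found for name in BACKBONE_ATOMS):
        return found["N"], found["CA"], found["C"]
    return None
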