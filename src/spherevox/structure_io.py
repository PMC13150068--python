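"""Parsing and cross-validation of paired PDB / TRIPOS MOL2 inputs.

The two files describe the same molecule: the PDB file carries coordinates
and residue bookkeeping, the MOL2 file carries SYBYL atom types (element +
hybridization, e.g. ``C.3`` for sp3 carbon) and the covalent bond list.
They are merged by ordinal position — the i-th accepted PDB atom pairs with
the i-th MOL2 atom — with a coordinate cross-check, into a single
residue-aware :class:`AnnotatedStructure` that all downstream voxelization
consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Mol2Atom",
    "BondRecord",
    "AnnotatedStructure",
    "parse_pdb",
    "parse_mol2",
    "simplify_sybyl",
    "merge_structure",
    "load_structure",
    "EmptyStructureError",
    "FormatError",
    "InconsistentAnnotationError",
]

#: The six canonical element categories carried by the occupancy channels.
CANONICAL_ELEMENTS = ("H", "C", "N", "O", "P", "S")

#: MOL2 bond-type codes that map onto the five counted bond classes.
_BOND_CODE_MAP = {
    "1": "single",
    "2": "double",
    "3": "triple",
    "ar": "aromatic",
    "am": "amide",
}

#: Residue names treated as water when excluding heteroatoms.
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class EmptyStructureError(ValueError):
    """The input contained no usable atom records."""


class FormatError(ValueError):
    """The input file violates the expected PDB/MOL2 layout."""


class InconsistentAnnotationError(ValueError):
    """The PDB and MOL2 files disagree; the structure is excluded."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom from a PDB file, in file order."""

    serial: int
    element_raw: str
    coords: tuple[float, float, float]
    chain_id: str
    residue_name: str
    residue_index: int
    altloc: str = ""
    is_hetero: bool = False
    atom_name: str = ""


@dataclass(frozen=True)
class Mol2Atom:
    """One atom from a TRIPOS MOL2 @<TRIPOS>ATOM section."""

    atom_id: int
    coords: tuple[float, float, float]
    sybyl_type: str


@dataclass(frozen=True)
class BondRecord:
    """A covalent bond between two MOL2 atom ids.

    ``bond_code`` is one of single / double / triple / aromatic / amide /
    other; only the five named classes are ever counted.
    """

    atom_a: int
    atom_b: int
    bond_code: str


@dataclass(frozen=True)
class MergedAtom:
    """A PDB atom enriched with its MOL2 SYBYL type and element category."""

    serial: int
    atom_id: int
    atom_name: str
    element_raw: str
    coords: tuple[float, float, float]
    chain_id: str
    residue_name: str
    residue_index: int
    sybyl_type: str
    element_category: str

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.residue_name)


@dataclass
class AnnotatedStructure:
    """The merged, chemically annotated, residue-aware atomic dataset."""

    protein_id: str
    atoms: list[MergedAtom]
    bonds: list[BondRecord]
    residue_order: list[tuple[str, int, str]] = field(default_factory=list)

    def coords_array(self) -> np.ndarray:
        """All retained coordinates as an (N, 3) float array."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_atoms(self, key: tuple[str, int, str]) -> list[MergedAtom]:
        return [a for a in self.atoms if a.residue_key == key]


def parse_pdb(path: str | os.PathLike, *, include_hetero: bool = False) -> list[AtomRecord]:
    """Parse ATOM (and optionally HETATM) records from a PDB file.

    Atoms are returned in file order.  For alternate locations the
    first-listed altloc of each atom name within a residue is kept and the
    rest are dropped, so every atom name appears at most once per residue.
    Waters are never included.
    """
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"could not read PDB file {path!r}: {exc}") from exc

    records: list[AtomRecord] = []
    if len(structure) == 0:
        raise EmptyStructureError(f"no atom records in {path!r}")
    model = structure[0]  # first model only, per single-conformer contract
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            if is_het and (not include_hetero or res.name in _WATER_NAMES):
                continue
            seen_names: set[str] = set()
            for atom in res:
                if atom.name in seen_names:
                    continue  # later-listed altloc of an already kept atom
                seen_names.add(atom.name)
                altloc = atom.altloc if atom.altloc != "\x00" else ""
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        element_raw=atom.element.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        altloc=altloc,
                        is_hetero=is_het,
                        atom_name=atom.name,
                    )
                )
    if not records:
        raise EmptyStructureError(f"no atom records in {path!r}")
    return records


def parse_mol2(path: str | os.PathLike) -> tuple[list[Mol2Atom], list[BondRecord]]:
    """Parse @<TRIPOS>ATOM and @<TRIPOS>BOND sections of a MOL2 file.

    Bond-type strings ``1 / 2 / 3 / ar / am`` map to single / double /
    triple / aromatic / amide; anything else (``un``, ``du``, ``nc``, ...)
    becomes ``other`` and is ignored by the bond counters.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            name = stripped[len("@<TRIPOS>"):].upper()
            current = sections.setdefault(name, [])
            continue
        if current is not None and stripped:
            current.append(stripped)

    if "ATOM" not in sections:
        raise FormatError(f"{path!r}: missing @<TRIPOS>ATOM section")
    if "BOND" not in sections:
        raise FormatError(f"{path!r}: missing @<TRIPOS>BOND section")

    atoms: list[Mol2Atom] = []
    for raw in sections["ATOM"]:
        parts = raw.split()
        if len(parts) < 6:
            raise FormatError(f"{path!r}: malformed ATOM line: {raw!r}")
        atoms.append(
            Mol2Atom(
                atom_id=int(parts[0]),
                coords=(float(parts[2]), float(parts[3]), float(parts[4])),
                sybyl_type=parts[5],
            )
        )
    ids = {a.atom_id for a in atoms}
    if len(ids) != len(atoms):
        raise FormatError(f"{path!r}: duplicate atom ids in ATOM section")

    bonds: list[BondRecord] = []
    for raw in sections["BOND"]:
        parts = raw.split()
        if len(parts) < 4:
            raise FormatError(f"{path!r}: malformed BOND line: {raw!r}")
        a, b = int(parts[1]), int(parts[2])
        if a not in ids or b not in ids:
            raise InconsistentAnnotationError(
                f"{path!r}: bond references unknown atom id {a if a not in ids else b}"
            )
        if a == b:
            raise FormatError(f"{path!r}: self-bond on atom {a}")
        code = _BOND_CODE_MAP.get(parts[3].lower(), "other")
        bonds.append(BondRecord(atom_a=a, atom_b=b, bond_code=code))
    return atoms, bonds


def simplify_sybyl(sybyl_type: str) -> str | None:
    """Reduce a SYBYL atom type to one of the six element categories.

    The element is the substring before the first ``.`` (``C.3`` -> ``C``,
    ``N.pl3`` -> ``N``, ``O.co2`` -> ``O``).  Elements outside
    {H, C, N, O, P, S} yield ``None``.  Total and idempotent.
    """
    if not sybyl_type:
        return None
    element = sybyl_type.split(".", 1)[0].strip().upper()
    return element if element in CANONICAL_ELEMENTS else None


def merge_structure(
    pdb_atoms: list[AtomRecord],
    mol2_atoms: list[Mol2Atom],
    bonds: list[BondRecord],
    coord_tolerance: float = 0.01,
    *,
    protein_id: str = "protein",
) -> AnnotatedStructure:
    """Pair PDB and MOL2 atoms ordinally into an :class:`AnnotatedStructure`.

    The i-th PDB atom is matched to the i-th MOL2 atom; any per-axis
    coordinate disagreement beyond ``coord_tolerance`` (Å), or a length
    mismatch, marks the annotation inconsistent and excludes the structure.
    Atoms whose element category falls outside {H, C, N, O, P, S} — taking
    the SYBYL simplification first and the PDB element column as fallback —
    are dropped together with their bonds.
    """
    if not pdb_atoms or not mol2_atoms:
        raise EmptyStructureError("cannot merge empty atom lists")
    if len(pdb_atoms) != len(mol2_atoms):
        raise InconsistentAnnotationError(
            f"atom count mismatch: PDB has {len(pdb_atoms)}, MOL2 has {len(mol2_atoms)}"
        )

    merged: list[MergedAtom] = []
    for pa, ma in zip(pdb_atoms, mol2_atoms):
        delta = max(abs(p - m) for p, m in zip(pa.coords, ma.coords))
        if delta > coord_tolerance:
            raise InconsistentAnnotationError(
                f"coordinate disagreement of {delta:.4f} Å at PDB serial "
                f"{pa.serial} / MOL2 atom {ma.atom_id} exceeds tolerance "
                f"{coord_tolerance} Å"
            )
        category = simplify_sybyl(ma.sybyl_type)
        if category is None:
            fallback = pa.element_raw.strip().upper()
            if fallback in CANONICAL_ELEMENTS:
                category = fallback
        if category is None:
            continue  # outside the six-element vocabulary: drop atom
        merged.append(
            MergedAtom(
                serial=pa.serial,
                atom_id=ma.atom_id,
                atom_name=pa.atom_name,
                element_raw=pa.element_raw,
                coords=pa.coords,
                chain_id=pa.chain_id,
                residue_name=pa.residue_name,
                residue_index=pa.residue_index,
                sybyl_type=ma.sybyl_type,
                element_category=category,
            )
        )
    if not merged:
        raise EmptyStructureError("no atoms retained after element filtering")

    retained_ids = {a.atom_id for a in merged}
    kept_bonds = [b for b in bonds if b.atom_a in retained_ids and b.atom_b in retained_ids]

    residue_order: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    for a in merged:
        key = a.residue_key
        if key not in seen:
            seen.add(key)
            residue_order.append(key)

    return AnnotatedStructure(
        protein_id=protein_id,
        atoms=merged,
        bonds=kept_bonds,
        residue_order=residue_order,
    )


def load_structure(
    pdb_path: str | os.PathLike,
    mol2_path: str | os.PathLike,
    *,
    coord_tolerance: float = 0.01,
    include_hetero: bool = False,
    protein_id: str | None = None,
) -> AnnotatedStructure:
    """Parse and merge a paired PDB/MOL2 input in one call."""
    if protein_id is None:
        protein_id = os.path.splitext(os.path.basename(os.fspath(pdb_path)))[0]
    pdb_atoms = parse_pdb(pdb_path, include_hetero=include_hetero)
    mol2_atoms, bonds = parse_mol2(mol2_path)
    return merge_structure(
        pdb_atoms, mol2_atoms, bonds, coord_tolerance, protein_id=protein_id
    )
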