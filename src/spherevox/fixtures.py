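"""Synthetic paired PDB/MOL2 toy peptides with known ground truth.

The generator emits small extended-chain peptides with idealized bond
lengths and angles (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å, C=O 1.23 Å),
identical atom order in both files, chemically sensible SYBYL types, and a
bond list with known type codes.  A ``ground_truth`` record accompanies the
text so parser and voxelizer outputs can be checked against construction.

Supported residue flavors: GLY (backbone only: N, Cα, C, O), ALA (adds Cβ),
SER (adds Cβ–Oγ), CYS (adds Cβ–Sγ), PHE (adds Cβ–Cγ–Cδ with an aromatic
Cγ–Cδ bond).  Consecutive residues are joined by amide C–N bonds.

The chain is built from one canonical backbone template repeated at an
integer lattice offset: every residue's backbone frame is then a pure
integer translation of the same pose, so an atom's fractional coordinates
on the default 1 Å lattice are identical in every residue frame.  Template
and decoration positions are chosen (deterministically, seeded by the
spec) so that each coordinate sits at least 0.05 Å away from the
half-spacing voxel-assignment boundaries in every frame; rigid-motion
invariance tests can therefore compare voxel tensors exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToySpec", "make_toy_peptide", "corrupt", "rigid_transform"]

# Idealized extended-chain geometry (Å).  ``chain_offset`` is the
# integer-component translation between consecutive residues; keeping it
# integer on the 1 Å lattice makes all residue frames translationally
# equivalent (see module docstring).  The N–Cα–C angle is solved at build
# time so the inter-residue C–N peptide bond has exactly length ``c_n``.
DEFAULT_GEOMETRY = {
    "n_ca": 1.46,
    "ca_c": 1.52,
    "c_n": 1.33,
    "c_o": 1.23,
    "chain_offset": (3, 1, 1),
}

_SYBYL = {
    "N": "N.am",
    "CA": "C.3",
    "C": "C.2",
    "O": "O.2",
    "CB": "C.3",
    "OG": "O.3",
    "SG": "S.3",
    "CG": "C.ar",
    "CD": "C.ar",
    "H": "H",
    "SE": "Se",
}

_ELEMENT = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
    "OG": "O", "SG": "S", "CG": "C", "CD": "C", "H": "H", "SE": "SE",
}

_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float], str]]] = {
    # residue -> list of (atom_name, bonded_to, offset from bonded atom, bond code)
    "GLY": [],
    "ALA": [("CB", "CA", (-0.28, 1.21, 0.87), "1")],
    "SER": [
        ("CB", "CA", (-0.28, 1.21, 0.87), "1"),
        ("OG", "CB", (0.36, 0.63, 1.18), "1"),
    ],
    "CYS": [
        ("CB", "CA", (-0.28, 1.21, 0.87), "1"),
        ("SG", "CB", (0.42, 0.74, 1.38), "1"),
    ],
    "PHE": [
        ("CB", "CA", (-0.28, 1.21, 0.87), "1"),
        ("CG", "CB", (0.36, 0.63, 1.18), "1"),
        ("CD", "CG", (1.12, 0.61, 0.23), "ar"),
    ],
}

_DEFAULT_CYCLE = ("ALA", "GLY", "SER", "CYS")


class ToySpecError(ValueError):
    """The toy-peptide specification is invalid."""


@dataclass
class ToySpec:
    """Specification for one synthetic toy peptide."""

    n_residues: int = 3
    residue_names: list[str] | None = None
    backbone_geometry: dict | None = None
    extra_atoms: list[tuple[str, tuple[float, float, float]]] = field(default_factory=list)
    seed: int = 0
    chain_id: str = "A"
    first_residue_index: int = 1
    protein_id: str = "toy_peptide"

    def resolved_names(self) -> list[str]:
        if self.residue_names is not None:
            if len(self.residue_names) != self.n_residues:
                raise ToySpecError("residue_names length must equal n_residues")
            names = [n.upper() for n in self.residue_names]
        else:
            names = [
                _DEFAULT_CYCLE[i % len(_DEFAULT_CYCLE)] for i in range(self.n_residues)
            ]
        for name in names:
            if name not in _SIDE_CHAINS:
                raise ToySpecError(f"unsupported residue flavor {name!r}")
        return names


#: Minimum distance (Å) of any local-frame coordinate from a half-spacing
#: voxel-assignment boundary at s = 1 Å; slack above 0.05 absorbs the
#: 3-decimal rounding of the emitted PDB text.
BOUNDARY_MARGIN = 0.06

_BACKBONE = ("N", "CA", "C")


def _frac_margin(pos) -> float:
    """Distance of each coordinate's fractional part from 0.5, minimized.

    Positions are rounded to the 3 decimals the PDB text carries, so the
    margin measured here is the margin the parsed fixture will have.
    """
    r = np.round(np.asarray(pos, dtype=float), 3)
    return float(np.min(np.abs((r % 1.0) - 0.5)))


def _solve_peptide_angle(d1: float, d2: float, c_n: float, delta: np.ndarray) -> float | None:
    """Find the Cα→C step angle giving inter-residue C–N distance ``c_n``.

    With N at the origin, Cα at (d1, 0, 0) and C at Cα + d2·(cos e, sin e, 0),
    the next residue's N sits at ``delta``; bisect on e so that
    ‖delta − C‖ = c_n.  Returns None when no solution exists in (10°, 85°).
    """
    def dist(e: float) -> float:
        c = np.array([d1 + d2 * math.cos(e), d2 * math.sin(e), 0.0])
        return float(np.linalg.norm(delta - c)) - c_n

    lo, hi = math.radians(10.0), math.radians(85.0)
    f_lo, f_hi = dist(lo), dist(hi)
    if f_lo * f_hi > 0:
        return None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if dist(lo) * dist(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _canonical_backbone(geo: dict, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Backbone template (N, Cα, C) expressed in its own frame.

    The template's frame is the identity by construction: centroid at the
    origin, N→Cα along +x, the N→Cα→C plane as the xy-plane.  Bond lengths
    are the ideal values, nudged by at most a few hundredths of an Å when a
    template coordinate would fall too close to an assignment boundary.
    """
    delta = np.asarray(geo["chain_offset"], dtype=float)
    if np.max(np.abs(delta - np.round(delta))) > 1e-12:
        raise ToySpecError("chain_offset must have integer components")
    for attempt in range(500):
        jitter = 0.0 if attempt == 0 else 0.02
        d1 = geo["n_ca"] + rng.uniform(-jitter, jitter)
        d2 = geo["ca_c"] + rng.uniform(-jitter, jitter)
        angle = _solve_peptide_angle(d1, d2, geo["c_n"], delta)
        if angle is None:
            continue
        n0 = np.zeros(3)
        ca0 = np.array([d1, 0.0, 0.0])
        c0 = ca0 + d2 * np.array([math.cos(angle), math.sin(angle), 0.0])
        centroid = (n0 + ca0 + c0) / 3.0
        template = {"N": n0 - centroid, "CA": ca0 - centroid, "C": c0 - centroid}
        if min(_frac_margin(p) for p in template.values()) >= BOUNDARY_MARGIN:
            return template
    raise ToySpecError("could not place backbone template away from voxel boundaries")


def _clear_position(parent_pos: np.ndarray, offset: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Parent + offset, resampled around the ideal offset until the
    position clears the assignment boundaries."""
    pos = parent_pos + offset
    sigma = 0.04
    for _ in range(500):
        if _frac_margin(pos) >= BOUNDARY_MARGIN:
            return pos
        pos = parent_pos + offset + rng.normal(0.0, sigma, 3)
        sigma = min(0.15, sigma * 1.05)
    raise ToySpecError("could not place atom away from voxel boundaries")


def _build_atoms(spec: ToySpec):
    """Lay out backbone + side chains; returns per-atom dicts and bonds."""
    if spec.n_residues < 1:
        raise ToySpecError("n_residues must be >= 1")
    geo = dict(DEFAULT_GEOMETRY)
    if spec.backbone_geometry:
        geo.update(spec.backbone_geometry)
    names = spec.resolved_names()
    rng = np.random.default_rng(spec.seed)
    template = _canonical_backbone(geo, rng)
    delta = np.asarray(geo["chain_offset"], dtype=float)

    atoms: list[dict] = []
    bonds: list[tuple[int, int, str]] = []
    index_of: dict[tuple[int, str], int] = {}

    def add_atom(res_i: int, res_name: str, atom_name: str, pos) -> int:
        atom_id = len(atoms) + 1
        atoms.append(
            {
                "atom_id": atom_id,
                "atom_name": atom_name,
                "element": _ELEMENT[atom_name],
                "sybyl": _SYBYL[atom_name],
                "coords": np.asarray(pos, dtype=float),
                "residue_name": res_name,
                "residue_index": spec.first_residue_index + res_i,
            }
        )
        index_of[(res_i, atom_name)] = atom_id
        return atom_id

    o_offset = geo["c_o"] * np.array([0.228, -0.601, 0.766])  # carbonyl direction
    for i, res_name in enumerate(names):
        shift = i * delta
        n_id = add_atom(i, res_name, "N", template["N"] + shift)
        ca_id = add_atom(i, res_name, "CA", template["CA"] + shift)
        c_id = add_atom(i, res_name, "C", template["C"] + shift)
        o_id = add_atom(
            i, res_name, "O",
            _clear_position(template["C"] + shift, o_offset, rng),
        )
        bonds.append((n_id, ca_id, "1"))
        bonds.append((ca_id, c_id, "1"))
        bonds.append((c_id, o_id, "2"))

        for atom_name, parent, offset, code in _SIDE_CHAINS[res_name]:
            parent_id = index_of[(i, parent)]
            parent_pos = atoms[parent_id - 1]["coords"]
            pos = _clear_position(parent_pos, np.asarray(offset, dtype=float), rng)
            new_id = add_atom(i, res_name, atom_name, pos)
            bonds.append((parent_id, new_id, code))

    # peptide bonds C(i) - N(i+1)
    for i in range(len(names) - 1):
        bonds.append((index_of[(i, "C")], index_of[(i + 1, "N")], "am"))

    # optional decorations hung off the first residue's CA
    for element, offset in spec.extra_atoms:
        element = element.upper()
        if element not in _SYBYL:
            raise ToySpecError(f"unsupported extra atom element {element!r}")
        ca_id = index_of[(0, "CA")]
        base = atoms[ca_id - 1]["coords"]
        pos = _clear_position(base, np.asarray(offset, dtype=float), rng)
        new_id = add_atom(0, names[0], element, pos)
        bonds.append((ca_id, new_id, "1"))

    return atoms, bonds, names


def _local_margins(atoms):
    """Per-atom worst distance from an assignment boundary over all frames.

    Independent re-derivation used by the generator's own tests: builds
    every residue's backbone frame explicitly and measures each atom's
    fractional distance from the half-spacing boundaries in that frame.
    """
    coords = np.array([np.round(a["coords"], 3) for a in atoms])
    margins = np.full(len(atoms), np.inf)
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a, c in zip(atoms, coords):
        if a["atom_name"] in _BACKBONE:
            by_res.setdefault(a["residue_index"], {})[a["atom_name"]] = c
    for bb in by_res.values():
        if len(bb) != 3:
            continue
        u = bb["CA"] - bb["N"]
        v = bb["C"] - bb["CA"]
        z = np.cross(u, v)
        if np.linalg.norm(z) < 1e-8:
            continue
        x = u / np.linalg.norm(u)
        z = z / np.linalg.norm(z)
        rot = np.vstack([x, np.cross(z, x), z])
        origin = (bb["N"] + bb["CA"] + bb["C"]) / 3.0
        local = (coords - origin) @ rot.T
        frame_margin = np.min(np.abs((local % 1.0) - 0.5), axis=1)
        margins = np.minimum(margins, frame_margin)
    return margins


def _format_pdb(atoms, spec: ToySpec) -> str:
    lines = []
    for a in atoms:
        name = a["atom_name"]
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a["coords"]
        lines.append(
            f"ATOM  {a['atom_id']:5d} {name_field} "
            f"{a['residue_name']:>3s} {spec.chain_id:1s}{a['residue_index']:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{a['element']:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _format_mol2(atoms, bonds, spec: ToySpec) -> str:
    lines = [
        "@<TRIPOS>MOLECULE",
        spec.protein_id,
        f" {len(atoms)} {len(bonds)} 1 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for a in atoms:
        x, y, z = a["coords"]
        lines.append(
            f"{a['atom_id']:>7d} {a['atom_name']:<4s} "
            f"{x:>9.4f} {y:>9.4f} {z:>9.4f} {a['sybyl']:<7s} "
            f"{a['residue_index']:>3d} {a['residue_name']}{a['residue_index']} 0.0000"
        )
    lines.append("@<TRIPOS>BOND")
    for i, (a, b, code) in enumerate(bonds, start=1):
        lines.append(f"{i:>6d} {a:>5d} {b:>5d} {code:>4s}")
    return "\n".join(lines) + "\n"


def make_toy_peptide(spec: ToySpec | None = None) -> tuple[str, str, dict]:
    """Generate a paired (pdb_text, mol2_text, ground_truth) toy peptide.

    ``ground_truth`` records the construction: atom table (ids, names,
    elements, rounded coordinates, residue keys), residue order, and the
    bond multiset with type codes — the oracle for round-trip tests.
    """
    spec = spec or ToySpec()
    atoms, bonds, names = _build_atoms(spec)
    pdb_text = _format_pdb(atoms, spec)
    mol2_text = _format_mol2(atoms, bonds, spec)
    ground_truth = {
        "protein_id": spec.protein_id,
        "n_atoms": len(atoms),
        "atoms": [
            {
                "atom_id": a["atom_id"],
                "atom_name": a["atom_name"],
                "element": a["element"],
                "sybyl": a["sybyl"],
                # coordinates as they appear in the PDB text (3 decimals)
                "coords": tuple(round(c, 3) for c in a["coords"]),
                "residue_key": (spec.chain_id, a["residue_index"], a["residue_name"]),
            }
            for a in atoms
        ],
        "residue_order": [
            (spec.chain_id, spec.first_residue_index + i, name)
            for i, name in enumerate(names)
        ],
        "bonds": [
            {"atom_a": a, "atom_b": b, "code": code} for a, b, code in bonds
        ],
    }
    return pdb_text, mol2_text, ground_truth


# ---------------------------------------------------------------------------
# Targeted corruption, for exercising exclusion/skip behavior
# ---------------------------------------------------------------------------

CORRUPT_MODES = ("drop_backbone_atom", "shift_mol2_atom", "drop_bond_section", "add_selenium")


def _pdb_atom_lines(pdb_text: str) -> list[str]:
    return [l for l in pdb_text.splitlines() if l.startswith(("ATOM", "HETATM"))]


def _mol2_sections(mol2_text: str) -> tuple[list[str], int, int]:
    """Return all lines plus [start, end) of the ATOM section body."""
    lines = mol2_text.splitlines()
    start = end = None
    for i, line in enumerate(lines):
        if line.strip() == "@<TRIPOS>ATOM":
            start = i + 1
        elif start is not None and line.strip().startswith("@<TRIPOS>"):
            end = i
            break
    if start is None:
        raise ValueError("no @<TRIPOS>ATOM section")
    return lines, start, (end if end is not None else len(lines))


def corrupt(pdb_text: str, mol2_text: str, mode: str) -> tuple[str, str]:
    """Inject one targeted defect into a paired toy structure.

    Modes: ``drop_backbone_atom`` removes a Cα from both files (second
    residue when present), ``shift_mol2_atom`` displaces one MOL2 atom by
    0.5 Å, ``drop_bond_section`` deletes the @<TRIPOS>BOND section,
    ``add_selenium`` appends a selenium atom (bonded in the MOL2) to both
    files.  Everything else is unchanged.
    """
    if mode not in CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {CORRUPT_MODES}")

    if mode == "shift_mol2_atom":
        lines, start, end = _mol2_sections(mol2_text)
        target = min(start + 2, end - 1)  # third atom when available
        parts = lines[target].split()
        parts[2] = f"{float(parts[2]) + 0.5:.4f}"
        lines[target] = " " + " ".join(parts)
        return pdb_text, "\n".join(lines) + "\n"

    if mode == "drop_bond_section":
        lines = mol2_text.splitlines()
        keep, skipping = [], False
        for line in lines:
            if line.strip() == "@<TRIPOS>BOND":
                skipping = True
                continue
            if skipping and line.strip().startswith("@<TRIPOS>"):
                skipping = False
            if not skipping:
                keep.append(line)
        return pdb_text, "\n".join(keep) + "\n"

    if mode == "drop_backbone_atom":
        atom_lines = _pdb_atom_lines(pdb_text)
        # choose the CA of the second residue if the chain has one
        residues_seen: list[int] = []
        target_id = None
        for line in atom_lines:
            resseq = int(line[22:26])
            if resseq not in residues_seen:
                residues_seen.append(resseq)
            if line[12:16].strip() == "CA" and (
                resseq == (residues_seen[1] if len(residues_seen) > 1 else residues_seen[0])
            ):
                target_id = int(line[6:11])
        if target_id is None:
            raise ValueError("no CA atom found to drop")
        new_pdb = "\n".join(
            l for l in pdb_text.splitlines()
            if not (l.startswith("ATOM") and int(l[6:11]) == target_id)
        ) + "\n"
        # drop the same ordinal atom and its bonds from the MOL2
        lines, start, end = _mol2_sections(mol2_text)
        kept, removed_id = [], None
        for line in lines[start:end]:
            if int(line.split()[0]) == target_id:
                removed_id = target_id
                continue
            kept.append(line)
        out = lines[:start] + kept
        in_bonds = False
        for line in lines[end:]:
            if line.strip() == "@<TRIPOS>BOND":
                in_bonds = True
                out.append(line)
                continue
            if in_bonds and line.strip() and not line.strip().startswith("@<TRIPOS>"):
                _, a, b = line.split()[:3]
                if int(a) == removed_id or int(b) == removed_id:
                    continue
            out.append(line)
        return new_pdb, "\n".join(out) + "\n"

    # add_selenium: append one Se atom near the last CA, in both files
    atom_lines = _pdb_atom_lines(pdb_text)
    last = atom_lines[-1]
    serial = int(last[6:11]) + 1
    ca_line = [l for l in atom_lines if l[12:16].strip() == "CA"][-1]
    x = float(ca_line[30:38]) + 1.3
    y = float(ca_line[38:46]) + 1.3
    z = float(ca_line[46:54]) + 0.3
    resname = ca_line[17:20]
    chain = ca_line[21]
    resseq = int(ca_line[22:26])
    se_pdb = (
        f"ATOM  {serial:5d}  SE  {resname} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          SE"
    )
    pdb_lines = pdb_text.splitlines()
    insert_at = max(i for i, l in enumerate(pdb_lines) if l.startswith("ATOM")) + 1
    pdb_lines.insert(insert_at, se_pdb)

    lines, start, end = _mol2_sections(mol2_text)
    ca_id = int(ca_line[6:11])
    se_line = (
        f"{serial:>7d} SE   {x:>9.4f} {y:>9.4f} {z:>9.4f} Se      "
        f"{resseq:>3d} {resname.strip()}{resseq} 0.0000"
    )
    lines.insert(end, se_line)
    n_bonds = sum(
        1 for l in lines if l.strip() and l.split()[0].isdigit() and False
    )  # bond renumbering not needed; ids are independent
    del n_bonds
    bond_ids = [
        int(l.split()[0])
        for i, l in enumerate(lines)
        if i > end and l.strip() and not l.strip().startswith("@<TRIPOS>")
    ]
    next_bond = (max(bond_ids) + 1) if bond_ids else 1
    lines.append(f"{next_bond:>6d} {ca_id:>5d} {serial:>5d}    1")
    return "\n".join(pdb_lines) + "\n", "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rigid transforms of the paired text, for invariance tests
# ---------------------------------------------------------------------------

def rigid_transform(
    pdb_text: str, mol2_text: str, rotation, translation
) -> tuple[str, str]:
    """Apply x → R·x + t to every coordinate in both files.

    ``rotation`` must be proper-orthonormal (RᵀR = I, det R = +1) within
    1e-9; reflections are rejected so invariance tests cannot silently pass
    a chirality flip through.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
        raise ValueError("rotation must be orthonormal within 1e-9")
    if abs(np.linalg.det(R) - 1.0) > 1e-9:
        raise ValueError("rotation must be proper (det = +1); reflections rejected")

    pdb_lines = []
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            nx, ny, nz = R @ xyz + t
            line = line[:30] + f"{nx:8.3f}{ny:8.3f}{nz:8.3f}" + line[54:]
        pdb_lines.append(line)

    lines, start, end = _mol2_sections(mol2_text)
    for i in range(start, end):
        parts = lines[i].split()
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        nx, ny, nz = R @ xyz + t
        parts[2], parts[3], parts[4] = f"{nx:.4f}", f"{ny:.4f}", f"{nz:.4f}"
        lines[i] = " " + " ".join(parts)
    return "\n".join(pdb_lines) + "\n", "\n".join(lines) + "\n"
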