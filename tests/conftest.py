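import numpy as np
import pytest

from spherevox.fixtures import ToySpec, make_toy_peptide
from spherevox.structure_io import AnnotatedStructure, MergedAtom, load_structure


@pytest.fixture(scope="session")
def tripeptide():
    """Default ALA-GLY-SER toy peptide: (pdb_text, mol2_text, ground_truth)."""
    return make_toy_peptide(ToySpec(n_residues=3))


@pytest.fixture(scope="session")
def tripeptide_paths(tmp_path_factory, tripeptide):
    pdb_text, mol2_text, _ = tripeptide
    root = tmp_path_factory.mktemp("toy")
    pdb_path = root / "toy_peptide.pdb"
    mol2_path = root / "toy_peptide.mol2"
    pdb_path.write_text(pdb_text)
    mol2_path.write_text(mol2_text)
    return pdb_path, mol2_path


@pytest.fixture(scope="session")
def tripeptide_structure(tripeptide_paths):
    return load_structure(*tripeptide_paths)


@pytest.fixture()
def write_pair(tmp_path):
    """Write (pdb_text, mol2_text) to disk; returns the two paths."""

    def _write(pdb_text, mol2_text, stem="pair"):
        pdb_path = tmp_path / f"{stem}.pdb"
        mol2_path = tmp_path / f"{stem}.mol2"
        pdb_path.write_text(pdb_text)
        mol2_path.write_text(mol2_text)
        return pdb_path, mol2_path

    return _write


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transformed_structure(
    structure: AnnotatedStructure, rotation: np.ndarray, translation: np.ndarray
) -> AnnotatedStructure:
    """In-memory rigid copy of a merged structure (full precision)."""
    atoms = []
    for a in structure.atoms:
        new = rotation @ np.asarray(a.coords) + translation
        atoms.append(
            MergedAtom(
                serial=a.serial,
                atom_id=a.atom_id,
                atom_name=a.atom_name,
                element_raw=a.element_raw,
                coords=tuple(new),
                chain_id=a.chain_id,
                residue_name=a.residue_name,
                residue_index=a.residue_index,
                sybyl_type=a.sybyl_type,
                element_category=a.element_category,
            )
        )
    return AnnotatedStructure(
        protein_id=structure.protein_id,
        atoms=atoms,
        bonds=list(structure.bonds),
        residue_order=list(structure.residue_order),
    )
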