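import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from grindqsar.structures import Molecule, from_rdkit, prepare


def mol_from_smiles(smiles: str, mol_id: str, seed: int = 7) -> Molecule:
    """Embedded 3D molecule with explicit hydrogens (deterministic)."""
    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    return from_rdkit(rdmol, mol_id)


@pytest.fixture(scope="session")
def methane():
    return mol_from_smiles("C", "methane")


@pytest.fixture(scope="session")
def benzene():
    return mol_from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def pyridine():
    return mol_from_smiles("c1ccncc1", "pyridine")


@pytest.fixture(scope="session")
def acetamide():
    return mol_from_smiles("CC(=O)N", "acetamide")


@pytest.fixture(scope="session")
def formaldehyde():
    return mol_from_smiles("C=O", "formaldehyde")


@pytest.fixture(scope="session")
def acetate():
    return mol_from_smiles("CC(=O)[O-]", "acetate")


@pytest.fixture(scope="session")
def benzene_prepared(benzene):
    return prepare(benzene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
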