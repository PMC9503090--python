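import numpy as np
import pytest
from rdkit import Chem

from cypqsar import FixtureSpec, gen_classification_fixture, \
    gen_regression_fixture


def reorder_smiles(smiles: str, rng: np.random.Generator) -> str:
    """Rewrite a SMILES with a random atom numbering (same molecule)."""
    mol = Chem.MolFromSmiles(smiles)
    perm = rng.permutation(mol.GetNumAtoms()).tolist()
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)


@pytest.fixture(scope="session")
def small_classification_set():
    """50-molecule noiseless planted-signal classification fixture."""
    cset, truth = gen_classification_fixture(
        FixtureSpec(n_molecules=50, seed=101, epsilon=0.0))
    return cset, truth


@pytest.fixture(scope="session")
def medium_classification_set():
    cset, truth = gen_classification_fixture(
        FixtureSpec(n_molecules=120, seed=7, epsilon=0.0))
    return cset, truth


@pytest.fixture(scope="session")
def regression_set_sigma03():
    rset, truth = gen_regression_fixture(
        FixtureSpec(n_molecules=120, seed=11, sigma=0.3))
    return rset, truth
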