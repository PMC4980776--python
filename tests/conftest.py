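import numpy as np
import pytest

from sigqsar import SyntheticSpec, generate_molecules, parse_smiles

# Structurally diverse fixture set: linear/branched alkanes, simple and
# fused aromatics, heteroaromatics, small rings, charged and multi-bonded
# species.
FIXTURE_SMILES = [
    "CCO",
    "CO",
    "CC(C)C",
    "CC(C)(C)C",
    "CCCCCC",
    "CC(C)CC(C)(C)C",
    "c1ccccc1",
    "c1ccc2ccccc2c1",
    "c1ccncc1",
    "c1ccc2[nH]ccc2c1",
    "C1CCCCC1",
    "C1CC1",
    "C1CCC2CCCCC2C1",
    "O=C(O)c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC#CC",
    "N#Cc1ccccc1",
    "C[N+](C)(C)C",
    "CC(=O)[O-]",
    "Oc1ccccc1",
    "CCOC(=O)CC",
    "C1COCCN1",
]


@pytest.fixture(scope="session")
def fixture_graphs():
    return [parse_smiles(s) for s in FIXTURE_SMILES]


@pytest.fixture(scope="session")
def small_molecule_pool():
    """Reusable pool of synthetic molecules for model-level tests."""
    return generate_molecules(SyntheticSpec(n_molecules=300, seed=99))


def random_permutations(n_atoms: int, count: int, seed: int):
    rng = np.random.default_rng(seed)
    return [rng.permutation(n_atoms).tolist() for _ in range(count)]
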