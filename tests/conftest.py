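import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dhtnn.graphio import featurize_molecule
from dhtnn.synthetic import SyntheticSpec, generate_smiles_set


@pytest.fixture(scope="session")
def small_molecules():
    """Valid SMILES with <= 12 heavy atoms, spanning rings and chains."""
    smiles = [s for s in generate_smiles_set(
        SyntheticSpec(n_molecules=60, seed=11))
        if featurize_molecule(s).n_atoms <= 12]
    assert len(smiles) >= 20
    return smiles[:25]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
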