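import numpy as np
import pytest

from tdpred.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset_400():
    """Shared synthetic structure-activity dataset (n=400, default conditions)."""
    return generate_dataset(GeneratorConfig(n_compounds=400, seed=11))


@pytest.fixture(scope="session")
def smiles_corpus(dataset_400):
    """200 standardized SMILES for molecule-level property tests."""
    return [r.smiles_std for r in dataset_400[:200]]


@pytest.fixture(scope="session")
def labels_400(dataset_400):
    return np.array([r.label for r in dataset_400])
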