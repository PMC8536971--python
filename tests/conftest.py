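import numpy as np
import pytest

from qsarflow import (
    QsarBenchSpec,
    compute_2d_descriptors,
    gen_qsar_dataset,
    gen_smiles_library,
)
from qsarflow.records import record_set_from_pairs


@pytest.fixture(scope="session")
def smiles_library():
    return gen_smiles_library(40, seed=11)


@pytest.fixture(scope="session")
def rdkit_matrix(smiles_library):
    return compute_2d_descriptors(smiles_library, backend="rdkit", keys=smiles_library)


@pytest.fixture(scope="session")
def linear_bench():
    spec = QsarBenchSpec(n=400, d=10, k=3, form="linear", noise_sd=0.3, seed=21)
    return gen_qsar_dataset(spec)


@pytest.fixture(scope="session")
def nonlinear_bench():
    spec = QsarBenchSpec(n=400, d=15, k=3, form="additive-nonlinear", noise_sd=0.3, seed=22)
    return gen_qsar_dataset(spec)


def keyed_set(source, pairs):
    """RecordSet over opaque keys (no RDKit), for curation arithmetic tests."""
    return record_set_from_pairs(source, pairs, keyed=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
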