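import numpy as np
import pytest

from ernascape import evaluate, run_pipeline, simulate


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic dataset (2 chromosomes x 2 Mb), fixed seed."""
    return simulate(seed=11)


@pytest.fixture(scope="session")
def result(dataset):
    return run_pipeline(dataset)


@pytest.fixture(scope="session")
def metrics(dataset, result):
    return evaluate(result, dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
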