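import pytest

from misdecode import genetic_code as gc
from misdecode.pam import load_matrix as load_pam
from misdecode.reference import load_reference_matrix
from misdecode.wobble import load_repertoire


@pytest.fixture(scope="session")
def repertoire():
    return load_repertoire()


@pytest.fixture(scope="session")
def properties():
    return gc.load_properties(gc.properties_path())


@pytest.fixture(scope="session")
def reference_matrix():
    return load_reference_matrix()


@pytest.fixture(scope="session")
def pam30():
    return load_pam()


@pytest.fixture(scope="session")
def pooled_simulations(repertoire):
    """200 replicate matrices drawn with the default class probabilities."""
    from misdecode.synthetic import GeneratorParams, generate_matrix

    return [
        generate_matrix(GeneratorParams(seed=1000 + i), repertoire)
        for i in range(200)
    ]
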