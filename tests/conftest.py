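import pytest

from pescreen.library import generate_sgrna_library
from pescreen.simulate import make_decoy_references
from pescreen.vector import build_screen_vector


@pytest.fixture(scope="session")
def spec():
    return build_screen_vector(seed=2)


@pytest.fixture(scope="session")
def library():
    return generate_sgrna_library(2, 3, 6, seed=2)


@pytest.fixture(scope="session")
def decoys():
    return make_decoy_references(2)
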