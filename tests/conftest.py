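import numpy as np
import pytest

from hml2ltr import synth


@pytest.fixture(scope="session")
def refs():
    """Synthetic subtype consensus trio + coordinate frame (fixed seed)."""
    return synth.simulate_subtype_references(seed=0)


@pytest.fixture(scope="session")
def consensus_refs(refs):
    return refs.refs()


@pytest.fixture(scope="session")
def frame(refs):
    return refs.frame


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
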