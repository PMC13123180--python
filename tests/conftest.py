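import copy

import pytest

from clarid import reference_codebook, load_conditions, worked_examples
from clarid.codebook import Codebook


@pytest.fixture(scope="session")
def cb():
    return reference_codebook()


@pytest.fixture(scope="session")
def conditions():
    return load_conditions()


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture()
def raw_codebook(cb):
    """A deep copy of the reference codebook document, safe to mutate."""
    return copy.deepcopy(cb.raw)


def rebuild(raw) -> Codebook:
    return Codebook.from_dict(raw)
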