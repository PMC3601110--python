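import random

import pytest

from agreemark import (
    GenerationConfig,
    Interpreter,
    PropertySpace,
    build_vocabulary,
    generate_ontology,
)


@pytest.fixture()
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def default_world():
    """One canonical world (5x3 attributes, 10 types) shared by read-only
    tests."""
    rng = random.Random(4242)
    ontology = generate_ontology(GenerationConfig(), rng)
    space = PropertySpace(ontology)
    vocabulary = build_vocabulary(ontology, rng, space, controller_fraction=0.5)
    return ontology, space, vocabulary


@pytest.fixture(scope="session")
def interpreter(default_world):
    ontology, _, _ = default_world
    return Interpreter(ontology)
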