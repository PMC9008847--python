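import random

import pytest

import wrkyfam as w


@pytest.fixture(scope="session")
def table1():
    return w.load_table1()


@pytest.fixture(scope="session")
def refs():
    return w.load_reference_domains()


@pytest.fixture(scope="session")
def small_genome():
    """A 12-gene synthetic genome with known family composition."""
    return w.gen_family_genome(12, seed=41)


@pytest.fixture()
def rng():
    return random.Random(20240)
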