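import numpy as np
import pytest

from sofmrbf import SyntheticSpec, generate, load_table1_fixture, load_table2_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2_records():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic table with its ground truth (seed 1)."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def synthetic_batch():
    """Tables for seeds 0..4, reused by the statistical property tests."""
    return [generate(SyntheticSpec(seed=s)) for s in range(5)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
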