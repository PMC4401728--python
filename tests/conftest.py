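import pytest

from agl import DependencyType, build_design, load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def exp1_nested():
    return build_design(1, DependencyType.NESTED, seed=11)


@pytest.fixture(scope="session")
def exp1_cross():
    return build_design(1, DependencyType.CROSS_SERIAL, seed=11)


@pytest.fixture(scope="session")
def exp2_nested():
    return build_design(2, DependencyType.NESTED, seed=11)


@pytest.fixture(scope="session")
def exp2_cross():
    return build_design(2, DependencyType.CROSS_SERIAL, seed=11)
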