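import pytest

from merolake.data import load_averno_2015, load_averno_chemistry, load_averno_gas


@pytest.fixture(scope="session")
def averno():
    """The joined 2015 Averno survey (18 depths, 0-34 m)."""
    return load_averno_2015()


@pytest.fixture(scope="session")
def averno_chemistry():
    return load_averno_chemistry()


@pytest.fixture(scope="session")
def averno_gas():
    return load_averno_gas()
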