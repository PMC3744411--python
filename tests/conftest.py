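import pytest

from vtanic.receptors import load_preset


@pytest.fixture(scope="session")
def a4b2():
    return load_preset("a4b2")


@pytest.fixture(scope="session")
def a7():
    return load_preset("a7")
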