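import pytest

from starmir import reference


@pytest.fixture(scope="session")
def mir146b_3p():
    return reference.MATURE_MIRNAS["hsa-miR-146b-3p"]


@pytest.fixture(scope="session")
def mir146b_5p():
    return reference.MATURE_MIRNAS["hsa-miR-146b-5p"]


@pytest.fixture(scope="session")
def mir127_3p():
    return reference.MATURE_MIRNAS["hsa-miR-127-3p"]


@pytest.fixture(scope="session")
def mir142_3p():
    return reference.MATURE_MIRNAS["hsa-miR-142-3p"]


@pytest.fixture(scope="session")
def prototype_design():
    return reference.prototype_146b_design()
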