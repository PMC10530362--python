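import pytest

from azoblock import (
    BlockRates,
    GatingRates,
    ThermoContext,
    preset,
)


@pytest.fixture(scope="session")
def thermo():
    return ThermoContext(296.0)


@pytest.fixture(scope="session")
def gating():
    return GatingRates()


@pytest.fixture(scope="session")
def block_rates():
    return BlockRates()


@pytest.fixture(scope="session")
def qaq_nmda():
    return preset("QAQ/NMDA/dark", kind="block").block


@pytest.fixture(scope="session")
def aaq_nmda():
    return preset("AAQ/NMDA/dark", kind="block").block


@pytest.fixture(scope="session")
def qaq_cp_ampa():
    return preset("QAQ/CP-AMPA/dark", kind="block").block


@pytest.fixture(scope="session")
def aaq_cp_ampa():
    return preset("AAQ/CP-AMPA/dark", kind="block").block
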