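import pytest

from retinorisk import build_coefficient_set, default_evidence_table


@pytest.fixture(scope="session")
def evidence():
    return default_evidence_table()


@pytest.fixture(scope="session")
def printed_coeffs(evidence):
    return build_coefficient_set(evidence, 0.278, mode="printed")


@pytest.fixture(scope="session")
def derived_coeffs(evidence):
    return build_coefficient_set(evidence, 0.278, mode="derived")
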