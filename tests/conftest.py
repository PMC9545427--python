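import logging

import pytest

import hyperoxr1 as hx


@pytest.fixture(scope="session")
def constants() -> hx.PhysiologicalConstants:
    return hx.PhysiologicalConstants()


@pytest.fixture(scope="session")
def blood_coeffs() -> hx.BloodModelCoefficients:
    logging.getLogger("hyperoxr1.constants").setLevel(logging.ERROR)
    return hx.placeholder_blood_coefficients()


@pytest.fixture(scope="session")
def relax_coeffs() -> hx.OxygenRelaxivityCoefficients:
    logging.getLogger("hyperoxr1.constants").setLevel(logging.ERROR)
    return hx.placeholder_relaxivity_coefficients()
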