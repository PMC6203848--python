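import numpy as np
import pytest

import oligoscribe as og


@pytest.fixture(scope="session")
def toy2_alphabet():
    """Minimal two-block alphabet used by the documented toy mass examples."""
    return og.Alphabet([og.BuildingBlock("A", 10.0), og.BuildingBlock("B", 20.0)])


@pytest.fixture(scope="session")
def toy_model():
    """Documented toy mass model: alpha 100, omega 50, offsets 1/2, no adduct."""
    return og.MassModel(
        alpha_mass=100.0,
        omega_mass=50.0,
        delta_left=1.0,
        delta_right=2.0,
        adduct_mass=0.0,
        charge=1,
    )


@pytest.fixture(scope="session")
def ref_alphabet():
    return og.reference_alphabet()


@pytest.fixture(scope="session")
def ref_model():
    return og.reference_mass_model()


@pytest.fixture(scope="session")
def ref_cfg(ref_alphabet):
    return og.reference_encoding_config(ref_alphabet)


@pytest.fixture(scope="session")
def reader_cfg():
    return og.reference_reader_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


SENTENCE = "TO WRITE OR NOT TO WRITE ON OLIGOS?".split()


@pytest.fixture(scope="session")
def sentence_words():
    return list(SENTENCE)
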