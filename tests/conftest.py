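import numpy as np
import pytest

import protomerkit as pk


@pytest.fixture(scope="session")
def toy_dimer_all_contacts():
    """Toy dimer with one planted contact of every detector class."""
    return pk.make_toy_dimer(
        6, 6, ["salt_bridge", "hbond", "pi_pi", "pi_cation", "apolar"])


@pytest.fixture(scope="session")
def salt_bridge_dimer():
    return pk.make_toy_dimer(8, 2, ["salt_bridge"], filler="SER")


@pytest.fixture()
def rng():
    return np.random.default_rng(20241)
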