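import numpy as np
import pytest

from wolbnet.fixtures import baseline_rates, demo_rates, sweep_rates


@pytest.fixture(scope="session")
def baseline():
    return baseline_rates()


@pytest.fixture(scope="session")
def demo():
    return demo_rates()


@pytest.fixture(scope="session")
def sweep():
    return sweep_rates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240112)
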