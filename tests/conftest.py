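import numpy as np
import pytest

from foldunits import FixtureSpec, ProteinRecord
from foldunits.fixtures import generate


@pytest.fixture(scope="session")
def small_dataset():
    """Ten proteins, planted units, no annotations — shared read-only."""
    return generate(FixtureSpec(n_proteins=10, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_protein():
    return ProteinRecord("toy", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK")
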