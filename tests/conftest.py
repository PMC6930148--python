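import numpy as np
import pytest

from succnet.containers import CommunityTable


@pytest.fixture
def tiny_table():
    """4 samples x 3 taxa with annotations, used across format tests."""
    return CommunityTable(
        ["s1", "s2", "s3", "s4"],
        ["bacA", "fungB", "eukC"],
        np.array([[3, 0, 1], [1, 2, 0], [5, 5, 5], [0, 0, 2]]),
        ["bacteria", "fungi", "small_eukaryote"],
        ["heterotrophic", "heterotrophic", "photosynthetic"],
    )


@pytest.fixture(scope="session")
def meta50():
    from succnet.simulate import simulate_environment_spatial
    return simulate_environment_spatial(50, seed=42)
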