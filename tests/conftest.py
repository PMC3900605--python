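import numpy as np
import pytest

from phagekit.simulate import CommunityConfig, simulate_phage_community


@pytest.fixture(scope="session")
def community():
    """Default three-group community with outgroup, seed 7."""
    return simulate_phage_community(CommunityConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
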