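import numpy as np
import pytest

from wdpscan.constants import CANONICAL_AA
from wdpscan.synthetic import SyntheticSpec, gen_proteome_fixture


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixture_proteome():
    """One medium synthetic proteome shared across tests (read-only)."""
    spec = SyntheticSpec(n_proteins=100, wdp_fraction=0.10, seed=11,
                         n_families=2, family_size=4)
    return gen_proteome_fixture(spec)
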