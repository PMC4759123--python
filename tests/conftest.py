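import numpy as np
import pytest

from protvarmap.fixtures import synth_structure
from protvarmap.pdbio import ResidueID
from protvarmap.variants import AA1


def make_ids(chain: str, numbers) -> list[ResidueID]:
    return [ResidueID(chain, n) for n in numbers]


@pytest.fixture
def small_structure():
    """Ten-residue extended chain with side chains, numbered 1..10."""
    return synth_structure("MKVRLHGWSA", make_ids("A", range(1, 11)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, n: int) -> str:
    return "".join(AA1[i] for i in rng.integers(0, len(AA1), size=n))
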