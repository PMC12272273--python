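import numpy as np
import pytest

from offscreen.fragmentation import DsRNAConstruct, SirnaFragment
from offscreen.synthetic_data import random_construct

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_fragment(residues: str, parent_id: str = "frag_parent",
                  start: int = 1, index: int = 0,
                  orientation: str = "sense") -> SirnaFragment:
    return SirnaFragment(parent_id=parent_id, start=start, k=len(residues),
                         residues=residues, orientation=orientation,
                         fragment_index=index)


@pytest.fixture(scope="session")
def construct_398() -> DsRNAConstruct:
    """A 398-nt construct with all 21-mers distinct (the headline geometry)."""
    return random_construct(398, rng_seed=11, distinct_kmers=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
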