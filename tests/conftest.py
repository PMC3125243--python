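import numpy as np
import pytest

from netcomm.network_genome import Genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def worked_example_genome():
    """A 13-gene network with eight terminal genes, four of them on.

    Genes 0-4 are internal (each regulates at least one downstream gene);
    genes 5-12 are terminals.  With root state 1 and all internal edges
    activating, the chosen terminal function bits leave terminals 5, 7, 9
    and 11 up-regulated, so the trait value is (140/8)*4 = 70.
    """
    heads = [-1, 0, 1, 2, 3, 0, 0, 0, 1, 1, 2, 3, 4]
    funcs = [0, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 1, 0]
    return Genome(heads, funcs, root_state=1)
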