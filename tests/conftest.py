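import numpy as np
import pytest

from liemarkov import Alignment, Phylogeny


@pytest.fixture
def four_taxon_tree():
    return Phylogeny.from_newick(
        "((a:0.2,b:0.35):0.15,(c:0.4,d:0.1):0.25);")


@pytest.fixture
def small_alignment():
    return Alignment.from_sequences(
        list("abcd"), ["ACGTAC", "AGGTAC", "ACCTTC", "TCGAAC"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
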