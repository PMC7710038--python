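import numpy as np
import pytest

from shiftscape import Alphabet, FitnessVector, MutationMatrix, parse_newick

# a hand-made 4-leaf tree with total branch length 8 (branch lengths fixed
# in-repo; only the leaf count and the total are constrained)
SIMPLE_NEWICK = "((A:1.5,B:1.5)E:1,(C:1.5,D:1.5)F:1)G;"


@pytest.fixture
def dna():
    return Alphabet("ACGT")


@pytest.fixture
def two_letter():
    return Alphabet("01")


@pytest.fixture
def simple_tree():
    return parse_newick(SIMPLE_NEWICK)


@pytest.fixture
def uniform_M(dna):
    return MutationMatrix.uniform(dna)


@pytest.fixture
def flat_F(dna):
    return FitnessVector(np.zeros(4), dna)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
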