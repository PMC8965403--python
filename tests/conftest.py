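import dendropy
import numpy as np
import pytest

from phylostab._treeindex import as_indexed
from phylostab.hmm import RateMatrix
from phylostab.trees import Taxonomy, sample_trees, taxonomy_from_string


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture
def balanced4():
    """Four-tip balanced tree with unit branch lengths."""
    return make_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def random_rates():
    def _make(rng: np.random.Generator) -> RateMatrix:
        v = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=8))
        return RateMatrix.from_vector(v)

    return _make


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random resolved ultrametric tree over tips t1..tn (root height 1)."""
    tax = taxonomy_from_string("(" + ",".join(f"t{i+1}" for i in range(n_tips)) + ");")
    return sample_trees(tax, 1, seed=int(rng.integers(0, 2**31 - 1)))[0]


@pytest.fixture
def study_taxonomy():
    """Five constrained families of the study's sizes (60 tips), unresolved
    within families and at the root."""
    fams = []
    for name, size in zip("ABCDE", (12, 2, 14, 11, 21)):
        fams.append("(" + ",".join(f"{name}{i+1}" for i in range(size)) + ")")
    return taxonomy_from_string("(" + ",".join(fams) + ");")
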