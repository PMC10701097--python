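import numpy as np
import pytest

from pkplace import PhyloKmerPlacer
from pkplace.seqio import Alignment, tree_from_string
from pkplace.substitution import get_model
from pkplace.synthetic_data import small_fixture


@pytest.fixture(scope="session")
def jc():
    return get_model("JC69")


@pytest.fixture(scope="session")
def small_data():
    """16 leaves x 600 bp DNA reference set (alignment, tree, spec)."""
    return small_fixture(seed=1)


@pytest.fixture(scope="session")
def small_placer(small_data):
    """Fitted placer on the 16-leaf fixture (default k=10); shared because
    the database build is the expensive step."""
    aln, tree, _ = small_data
    return PhyloKmerPlacer().fit(aln, tree)


@pytest.fixture
def toy_alignment():
    return Alignment(
        names=["A", "B", "C"],
        rows=["ACGTA", "ACGTA", "ACCTA"],
        alphabet="DNA",
    )


@pytest.fixture
def cherry_tree():
    """((A,B),C) with known branch lengths."""
    return tree_from_string("((A:2.0,B:4.0):1.0,C:1.5);")


def random_distribution_rows(rng, k, sigma):
    """k rows of strictly positive state distributions."""
    w = rng.dirichlet(np.ones(sigma) * 0.5, size=k) + 1e-6
    return w / w.sum(axis=1, keepdims=True)
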