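import numpy as np
import pytest

from bigtree.alignment import Alignment, compress_patterns
from bigtree.model import gamma_discretize, jc_params
from bigtree.simulate import DEFAULT_GTR, simulate_alignment, simulate_tree, \
    inject_structured_gaps


@pytest.fixture
def gtr():
    return DEFAULT_GTR


@pytest.fixture
def jc():
    return jc_params()


@pytest.fixture
def gamma4():
    return gamma_discretize(0.7, 4)


def make_instance(n, sites, seed, alpha=0.7, params=DEFAULT_GTR,
                  gappyness=0.0, genes=6, mean_branch_length=0.08):
    """Random tree + (optionally block-gapped) alignment + patterns."""
    tree = simulate_tree(n, seed, mean_branch_length=mean_branch_length)
    aln = simulate_alignment(tree, params, alpha, sites, seed + 1000)
    if gappyness > 0.0:
        aln, _ = inject_structured_gaps(aln, genes, 1.0 - gappyness,
                                        seed + 2000)
    return tree, aln, compress_patterns(aln)


@pytest.fixture
def small_instance():
    return make_instance(10, 120, seed=7)
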