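import numpy as np
import pytest

from acctrait import (
    make_full_binary_tree,
    parse_newick,
    jukes_cantor,
    RateMultipliers,
    VarianceParams,
    TransitionParams,
)
from acctrait.element_io import ElementData, initialize_latent


@pytest.fixture
def jc():
    return jukes_cantor()


@pytest.fixture
def tree3():
    """((A,B),C): L=3, N=5, root=4."""
    return parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")


@pytest.fixture
def tree4():
    """Balanced 4-leaf tree."""
    return make_full_binary_tree(2, 0.15)


@pytest.fixture
def tree2():
    return parse_newick("(A:0.3,B:0.2);")


@pytest.fixture
def default_params():
    return (
        TransitionParams(a=0.3, b=0.4, c=0.5),
        RateMultipliers(r2=0.2, r3=2.0),
        VarianceParams(sigma2=1.0, beta2=0.5, beta3=2.0),
    )


def make_element(tree, model, rng, S=2, y_leaves=None, X_leaves=None):
    """Construct an ElementData directly from arrays (test helper)."""
    L, N = tree.n_leaves, tree.n_nodes
    X = np.full((N, S), 0, dtype=np.int8)
    if X_leaves is not None:
        X[:L] = X_leaves
    else:
        X[:L] = rng.integers(0, 4, size=(L, S))
    y = np.zeros(N)
    observed = np.ones(L, dtype=bool)
    if y_leaves is not None:
        y[:L] = y_leaves
    else:
        y[:L] = rng.standard_normal(L)
    el = ElementData(X=X, y=y, observed_trait=observed)
    initialize_latent(el, tree, model, rng)
    return el
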