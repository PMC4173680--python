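import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def rooted(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted")


@pytest.fixture
def tree_factory():
    return rooted


@pytest.fixture(scope="session")
def small_study():
    """One default 40-species synthetic study, shared across tests."""
    from attini.synthetic_data import make_study
    return make_study(seed=7)


def random_mrp_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int,
                      missing_rate: float = 0.15):
    """Random informative binary matrix with missing entries."""
    from attini.supertree import MRPMatrix
    while True:
        X = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
        X[rng.random((n_taxa, n_chars)) < missing_rate] = -1
        if all((X[:, j] == 1).any() and (X[:, j] == 0).any()
               for j in range(n_chars)):
            return MRPMatrix([f"x{i}" for i in range(n_taxa)], X,
                             np.ones(n_chars))
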