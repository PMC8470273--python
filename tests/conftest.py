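import numpy as np
import pytest

from karyoevo import KaryotypeFormula, PhyloTree, paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Built-in curated records and the fixture phylogeny."""
    return paper_fixtures()


@pytest.fixture(scope="session")
def fixture_records(fixtures):
    return fixtures[0]


@pytest.fixture(scope="session")
def fixture_tree(fixtures):
    return fixtures[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_formula(rng: np.random.Generator, n_pairs: int | None = None) -> KaryotypeFormula:
    """A uniform random composition of n pairs into the four classes."""
    n = n_pairs if n_pairs is not None else int(rng.integers(1, 33))
    cuts = np.sort(rng.integers(0, n + 1, size=3))
    return KaryotypeFormula(
        {
            "m": int(cuts[0]),
            "sm": int(cuts[1] - cuts[0]),
            "st": int(cuts[2] - cuts[1]),
            "t": int(n - cuts[2]),
        }
    )


def small_tree(newick: str) -> PhyloTree:
    return PhyloTree.from_newick(newick)
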