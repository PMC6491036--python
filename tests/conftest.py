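import numpy as np
import pandas as pd
import pytest

from phylofoot import morphometrics as M
from phylofoot.synthetic import make_fixture, make_tree, packaged_tree
from phylofoot.tree import read_newick


@pytest.fixture(scope="session")
def tree3():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star8():
    return read_newick("(" + ",".join(f"T{i}:1" for i in range(1, 9)) + ");")


@pytest.fixture(scope="session")
def balanced8():
    return read_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


@pytest.fixture(scope="session")
def fixture_tree():
    return packaged_tree()


@pytest.fixture(scope="session")
def bd20():
    return make_tree(20, "birth-death", seed=11)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study under the heel-strike-plantigrade scenario."""
    return make_fixture("h4", seed=1)


@pytest.fixture(scope="session")
def study_pc_means(study):
    std = M.geomean_standardize(study.measurements)
    res = M.pca(std)
    return M.species_means(res.scores)[["PC1", "PC2", "PC3"]]


def random_tree(n, seed):
    return make_tree(n, "birth-death", seed=seed)


def random_traits(tree, seed, n_traits=1, scale=1.0):
    rng = np.random.default_rng(seed)
    cols = [f"trait{j + 1}" for j in range(n_traits)]
    return pd.DataFrame(
        scale * rng.standard_normal((tree.n_tips, n_traits)),
        index=tree.tip_labels,
        columns=cols,
    )
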