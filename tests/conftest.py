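import numpy as np
import pytest

from phyloconv.shapes import TraitMatrix
from phyloconv.synthetic_data import (
    SimulationScenario,
    make_convergence_scenario,
    simulate_yule_tree,
)
from phyloconv.treeio import parse_newick


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def balanced_four_traits():
    return TraitMatrix(["A", "B", "C", "D"],
                       [[0.0], [4.0], [0.0], [-4.0]])


@pytest.fixture
def yule_tree_12():
    return simulate_yule_tree(12, seed=42, depth_rescale=10.0)


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down planted-convergence scenario for integration tests."""
    return make_convergence_scenario(
        SimulationScenario(seed=11, n_tips=20, n_focal=4))


def random_trait_matrix(tree, rng, m=2):
    labels = tree.tip_labels
    return TraitMatrix(labels, rng.standard_normal((len(labels), m)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
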