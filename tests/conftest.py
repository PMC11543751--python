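import numpy as np
import pandas as pd
import pytest

from glmmtree.data_model import LongitudinalDataset, PartitionTree, Split, TreeNode
from glmmtree.simulate import SimulationDesign, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Small four-subgroup dataset (N=60) from the built-in generator."""
    design = SimulationDesign(N=60, sigma_b0_sq=1.0, sigma_b1_sq=0.1, n_noise=2, rho=0.0)
    data, truth = simulate_dataset(design, seed=7)
    return data, truth


@pytest.fixture
def medium_dataset():
    """Study-sized dataset (N=250) for recovery checks."""
    design = SimulationDesign(N=250, sigma_b0_sq=1.0, sigma_b1_sq=0.1, n_noise=5, rho=0.0)
    data, truth = simulate_dataset(design, seed=11)
    return data, truth


def make_truth_tree() -> PartitionTree:
    """The generating partition: u1 first, then u2 (left) and u3 (right).

    Terminal nodes in preorder: 3 = (u1=0, u2<=0), 4 = (u1=0, u2>0),
    6 = (u1=1, u3<=0), 7 = (u1=1, u3>0).
    """
    nodes = {
        1: TreeNode(node_id=1, depth=0,
                    split=Split("u1", "categorical", left_levels=(0,), right_levels=(1,)),
                    children=(2, 5)),
        2: TreeNode(node_id=2, depth=1, split=Split("u2", "numeric", threshold=0.0),
                    children=(3, 4)),
        3: TreeNode(node_id=3, depth=2, beta=(0.0, 0.75)),
        4: TreeNode(node_id=4, depth=2, beta=(1.5, 1.5)),
        5: TreeNode(node_id=5, depth=1, split=Split("u3", "numeric", threshold=0.0),
                    children=(6, 7)),
        6: TreeNode(node_id=6, depth=2, beta=(3.0, 2.25)),
        7: TreeNode(node_id=7, depth=2, beta=(4.5, 3.0)),
    }
    return PartitionTree(nodes=nodes, root_id=1)


@pytest.fixture
def truth_tree():
    return make_truth_tree()


#: terminal node id -> generator subgroup index
TRUTH_LEAF_TO_SUBGROUP = {3: 0, 4: 1, 6: 2, 7: 3}


@pytest.fixture
def toy_long_frame():
    """5 subjects x 5 timepoints with one numeric and one categorical covariate."""
    rng = np.random.default_rng(3)
    rows = []
    for s in range(5):
        grp = "a" if s < 2 else "b"
        x = float(s)
        for t in range(5):
            rows.append({"subject": f"s{s}", "time": float(t),
                         "y": 1.0 + 0.5 * t + rng.normal(), "grp": grp, "x": x})
    return pd.DataFrame(rows)
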