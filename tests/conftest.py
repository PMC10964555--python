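import numpy as np
import pandas as pd
import pytest

from urbiome import synthetic as syn
from urbiome.trees import PhyloTree


@pytest.fixture(scope="session")
def cherry_tree() -> PhyloTree:
    """((A:1,B:1):1,C:2); — the smallest tree with hand-checkable paths."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star_tree() -> PhyloTree:
    """Five tips, all at distance 1 from the root (distance 2 pairwise)."""
    return PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def two_clade_tree() -> PhyloTree:
    """Eight tips in two well-separated clades of four."""
    left = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):1"
    right = "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1):1"
    return PhyloTree.from_newick(f"({left},{right});")


@pytest.fixture(scope="session")
def sim_tree() -> PhyloTree:
    return syn.simulate_tree(64, seed=11)


@pytest.fixture(scope="session")
def random_table(sim_tree) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 25, size=(6, sim_tree.n_tips))
    counts[0, : sim_tree.n_tips // 2] = 0
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(6)],
        columns=sim_tree.tip_labels,
    )
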