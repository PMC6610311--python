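import numpy as np
import pandas as pd
import pytest

from assemblage.io import CommunityTable, PhyloTree, read_newick
from assemblage.phylo import PairwiseDistanceMatrix, cophenetic_matrix

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_tip_tree(tmp_path) -> PhyloTree:
    path = tmp_path / "four.nwk"
    path.write_text(FOUR_TIP_NEWICK + "\n")
    return read_newick(path)


@pytest.fixture
def four_tip_dist(four_tip_tree) -> PairwiseDistanceMatrix:
    return cophenetic_matrix(four_tip_tree, labels=["A", "B", "C", "D"])


def abund(dist, **taxa):
    """Abundance vector over dist.labels from keyword taxon counts."""
    x = np.zeros(len(dist.labels))
    for name, value in taxa.items():
        x[dist.labels.index(name)] = value
    return x


def make_table(counts: dict, taxa: list[str]) -> CommunityTable:
    return CommunityTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"), dtype=np.int64)
    )


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree with uniform random branch lengths (Newick)."""
    nodes = [f"T{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


@pytest.fixture
def random_tree_factory(tmp_path):
    def factory(seed: int, n_tips: int) -> PhyloTree:
        rng = np.random.default_rng(seed)
        path = tmp_path / f"rand_{seed}_{n_tips}.nwk"
        path.write_text(random_tree_newick(rng, n_tips) + "\n")
        return read_newick(path)

    return factory
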