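import numpy as np
import pytest

from venomdyn.core_io import Phylogeny, read_newick


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — ultrametric, height 2."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip_tree() -> Phylogeny:
    return read_newick("(A:1,B:1);")


@pytest.fixture
def six_tip_tree() -> Phylogeny:
    return read_newick(
        "(((A:0.3,B:0.3):0.3,(C:0.4,D:0.4):0.2):0.4,(E:0.8,F:0.8):0.2);"
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random rooted binary tree (not necessarily ultrametric) for oracles."""
    # grow by repeatedly splitting a random tip; parent arrays built at the end
    from venomdyn.simulate import simulate_tree

    tree = simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    # perturb branch lengths so trees are non-ultrametric where allowed
    blen = tree.branch_lengths * rng.uniform(0.5, 1.5, tree.n_nodes)
    blen[tree.root] = 0.0
    return Phylogeny(tree.parent, blen, tree.tip_labels)


def brute_force_covariance(tree: Phylogeny) -> np.ndarray:
    """O(n^2 depth) path-sum oracle for the BM covariance matrix."""
    n = tree.n_tips
    depths = tree.node_depths()

    def ancestors(i):
        out = []
        while i >= 0:
            out.append(i)
            i = int(tree.parent[i])
        return out

    C = np.zeros((n, n))
    for i in range(n):
        anc_i = set(ancestors(i))
        for j in range(n):
            if i == j:
                C[i, j] = depths[i]
            else:
                k = j
                while k not in anc_i:
                    k = int(tree.parent[k])
                C[i, j] = depths[k]
    return C
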