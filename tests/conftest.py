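import dendropy
import numpy as np
import pytest

from hydrophylo import trees as htrees


@pytest.fixture(scope="session")
def tree8():
    return htrees.simulate_yule_tree(8, seed=5)


@pytest.fixture(scope="session")
def tree16():
    return htrees.simulate_yule_tree(16, seed=11)


@pytest.fixture(scope="session")
def tree32():
    return htrees.simulate_yule_tree(32, seed=123)


@pytest.fixture()
def balanced4():
    """Fixed 4-taxon tree with hand-listed branch lengths."""
    t = dendropy.Tree.get(
        data="((A:0.3,B:0.3):0.7,(C:0.5,D:0.5):0.5);", schema="newick",
        preserve_underscores=True)
    t.is_rooted = True
    return t


def brute_force_vcv(tree):
    """Independent oracle for the phylogenetic covariance matrix.

    Enumerates root-to-node path lengths by walking ancestor chains and
    takes, for each leaf pair, the depth of the deepest shared ancestor.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    def chain(node):
        out = []
        depth = 0.0
        cur = node
        path = []
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        # accumulate depths root-down
        d = 0.0
        for nd in reversed(path):
            if nd.parent_node is not None:
                d += nd.edge.length or 0.0
            out.append((nd, d))
        return out

    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        ci = chain(leaves[i])
        V[i, i] = ci[-1][1]
        anc_i = {id(nd): d for nd, d in ci}
        for j in range(i + 1, n):
            best = 0.0
            for nd, d in chain(leaves[j]):
                if id(nd) in anc_i:
                    best = max(best, d)
            V[i, j] = V[j, i] = best
    return V, labels
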