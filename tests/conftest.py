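import random

import numpy as np
import pytest

from haploblock.phylo import DistanceMatrix, Node, Tree


def random_binary_tree(n_taxa: int, rng: random.Random) -> Tree:
    """Random unrooted binary tree with uniform branch lengths in [0.1, 1]."""
    nodes = [Node(f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = rng.uniform(0.1, 1.0)
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        parent = Node()
        parent.length = rng.uniform(0.1, 1.0)
        parent.children = [nodes[i], nodes[j]]
        del nodes[i]
        del nodes[j]
        nodes.append(parent)
    root = Node()
    root.children = nodes
    return Tree(root)


def additive_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additive by construction)."""
    paths = {}

    def walk(node, dist_from_root):
        if node.is_leaf():
            paths[node.name] = dist_from_root + node.length
        for c in node.children:
            walk(c, dist_from_root + (node.length if node is not tree.root else 0.0))

    # compute distances pairwise via lowest common ancestor walk: simpler to
    # collect root-to-leaf paths as edge sets
    edges = {}

    def collect(node, path):
        if node.is_leaf():
            edges[node.name] = path + [(id(node), node.length)]
            return
        for c in node.children:
            collect(c, path + ([(id(node), node.length)] if node is not tree.root else []))

    collect(tree.root, [])
    taxa = sorted(edges)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = dict(edges[taxa[i]])
            pj = dict(edges[taxa[j]])
            shared = set(pi) & set(pj)
            dist = sum(L for nid, L in pi.items() if nid not in shared) + sum(
                L for nid, L in pj.items() if nid not in shared
            )
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, d=d)


@pytest.fixture
def rng():
    return random.Random(20160915)
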