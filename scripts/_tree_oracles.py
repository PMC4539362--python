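"""Random-tree generation and independent oracles used by the acceptance run."""

import itertools

import numpy as np

from haploblock.phylo import DistanceMatrix, Node, Tree


def random_binary_tree(n_taxa, rng):
    """Random unrooted binary tree with branch lengths uniform in [0.1, 1]."""
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


def additive_matrix(tree):
    """Leaf-to-leaf path-length matrix (additive by construction)."""
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
            d[i, j] = d[j, i] = sum(
                L for nid, L in pi.items() if nid not in shared
            ) + sum(L for nid, L in pj.items() if nid not in shared)
    return DistanceMatrix(taxa=taxa, d=d)


def brute_force_bipartitions(tree):
    """Split enumeration via adjacency-graph edge cuts (networkx route)."""
    import networkx as nx

    g = nx.Graph()
    counter = itertools.count()

    def walk(node, parent_id):
        nid = next(counter) if not node.is_leaf() else node.name
        g.add_edge(parent_id, nid)
        for c in node.children:
            walk(c, nid)

    g.add_node("root")
    for c in tree.root.children:
        walk(c, "root")
    leaves = set(tree.leaf_names())
    ref = min(leaves)
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(x for x in comp if x in leaves)
        g.add_edge(u, v)
        if 1 < len(side) < len(leaves) - 1:
            side = side if ref not in side else frozenset(leaves - side)
            splits.add(side)
    return splits
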